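"""End-to-end orchestration: config -> ranges, RI matrices, reports.

A single structured config (dict or YAML) describes either a synthetic
landscape + virtual species or file inputs (ASCII rasters + occurrence
CSV), the modelling knobs, and the scenario shifts.  ``run_pipeline``
composes the stages

    load/generate -> clip/thin -> screen -> fit replicate ensembles ->
    binarize -> project per scenario -> overlap/identity statistics ->
    RI matrices -> report

with every random step seeded from one master seed, and writes CSV
tables, ASCII rasters and a JSON run manifest under the output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import landscape as ls
from . import raster as rio
from .isolation import IsolationMatrix, isolation_matrix, area_dynamics, \
    isolation_shift_summary
from .overlap import identity_test, levins_B, normalize, schoener_D, warren_I
from .screening import screen
from .sdm import EnsembleNicheModel, sample_background

DEFAULT_CONFIG = {
    "seed": 0,
    "landscape": {"n_rows": 80, "n_cols": 80, "spatial_range": 5.0},
    "species": [],
    "scenarios": [],
    "window": None,                      # [lon_min, lon_max, lat_min, lat_max]
    "screening": {"r_threshold": 0.75, "vif_threshold": 10.0},
    "modeling": {
        "families": ["GLM", "MAXENT_LIKE", "MARS_LIKE"],
        "n_replicates": 10,
        "n_background": 10_000,
        "train_frac": 0.7,
        "tss_min": 0.8,
    },
    "identity_test": {"enabled": False, "n_reps": 99, "model_family": "GLM"},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        import yaml
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ScenarioReport:
    """Everything the pipeline computed, plus its provenance manifest."""

    config: dict
    areas: pd.DataFrame                       # area_dynamics table
    matrices: dict[str, IsolationMatrix]      # per scenario incl. "current"
    shifts: dict[str, pd.DataFrame]           # per non-current scenario
    overlap: pd.DataFrame                     # pairwise D, I (+ identity test)
    breadth: pd.DataFrame                     # Levins' B per species
    screening: object
    manifest: dict
    ensembles: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = [f"Ecogeographic isolation report "
                 f"(seed {self.manifest['seed']}, "
                 f"config {self.manifest['config_hash']})",
                 f"  species: {', '.join(self.matrices['current'].species)}",
                 f"  scenarios: {', '.join(self.matrices)}"]
        for name, m in self.matrices.items():
            lines.append(f"  mean RI [{name}]: {m.mean_ri():.4f}")
        return "\n".join(lines)


def _species_from_config(cfg: dict) -> list[ls.VirtualSpecies]:
    out = []
    for sp in cfg["species"]:
        out.append(ls.VirtualSpecies(
            sp["name"], dict(sp["niche_center"]), dict(sp["niche_breadth"]),
            sp.get("max_suitability", 1.0)))
    return out


def _prepare_synthetic(cfg: dict, rng) -> tuple[rio.EnvStack, list, dict]:
    spec_kwargs = dict(cfg["landscape"])
    spec_kwargs.setdefault("seed", int(rng.integers(2 ** 31)))
    if "layer_names" in spec_kwargs:
        spec_kwargs["layer_names"] = tuple(spec_kwargs["layer_names"])
    if "extent" in spec_kwargs:
        spec_kwargs["extent"] = tuple(spec_kwargs["extent"])
    spec = ls.LandscapeSpec(**spec_kwargs)
    env = ls.gen_env_stack(spec)
    occ_sets = []
    for sp_cfg, sp in zip(cfg["species"], _species_from_config(cfg)):
        suit = ls.true_suitability(env, sp)
        occ = ls.sample_occurrences(
            suit, env, int(sp_cfg.get("n_occurrences", 100)),
            seed=int(rng.integers(2 ** 31)), species=sp.name)
        occ_sets.append(occ)
    scen_stacks = {}
    for sc in cfg["scenarios"]:
        shift = ls.ScenarioShift(sc["name"],
                                 dict(sc.get("additive_offsets", {})),
                                 dict(sc.get("multiplicative_factors", {})))
        scen_stacks[shift.name] = ls.apply_scenario(env, shift)
    return env, occ_sets, scen_stacks


def _prepare_from_files(cfg: dict) -> tuple[rio.EnvStack, list, dict]:
    data = cfg["data"]
    env = rio.read_stack(data["raster_dir"], data.get("layer_names"))
    occ_sets, _ = rio.read_occurrences(data["occurrences_csv"])
    scen_stacks = {}
    for name, d in data.get("scenario_dirs", {}).items():
        dirs = [d] if isinstance(d, (str, Path)) else list(d)
        stacks = [rio.read_stack(p, data.get("layer_names")) for p in dirs]
        from .sdm import average_scenarios
        scen_stacks[name] = average_scenarios(stacks)
    return env, occ_sets, scen_stacks


def run_pipeline(config, outdir=None) -> ScenarioReport:
    cfg = load_config(config)
    master_seed = int(cfg["seed"])
    rng = np.random.default_rng(master_seed)
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def fail(stage, e):
        if outdir:
            (outdir / "FAILED").write_text(f"{stage}: {e}\n")
        raise StageError(stage, e)

    # -- load or generate ---------------------------------------------
    try:
        if "data" in cfg and cfg["data"]:
            env, occ_sets, scen_stacks = _prepare_from_files(cfg)
        else:
            env, occ_sets, scen_stacks = _prepare_synthetic(cfg, rng)
    except StageError:
        raise
    except Exception as e:
        fail("load", e)

    # -- clip + thin --------------------------------------------------
    try:
        if cfg.get("window"):
            w = cfg["window"]
            env = rio.clip_window(env, *w)
            scen_stacks = {k: rio.clip_window(v, *w)
                           for k, v in scen_stacks.items()}
        occ_sets = [rio.thin_to_grid(o, env) for o in occ_sets]
        for o in occ_sets:
            if len(o) < 2:
                raise ValueError(f"species '{o.species}' has < 2 usable records")
    except Exception as e:
        fail("prepare", e)

    # -- predictor screening ------------------------------------------
    try:
        tables = [rio.extract_at_points(env, o)[0].drop(columns=["lon", "lat"])
                  for o in occ_sets]
        pooled = pd.concat(tables, ignore_index=True)
        scr = screen(pooled, cfg["screening"]["r_threshold"],
                     cfg["screening"]["vif_threshold"])
        retained = scr.retained if len(scr.retained) >= 2 else env.layer_names
        env_model = rio.EnvStack({k: env.layers[k] for k in retained},
                                 env.mask.copy(), env.transform)
        scen_model = {name: rio.EnvStack(
            {k: s.layers[k] for k in retained}, s.mask.copy(), s.transform)
            for name, s in scen_stacks.items()}
    except Exception as e:
        fail("screen", e)

    # -- ensembles + binarization + projection ------------------------
    mcfg = cfg["modeling"]
    ensembles, ranges, areas = {}, {"current": {}}, {"current": {}}
    try:
        background = sample_background(env_model, int(mcfg["n_background"]),
                                       seed=int(rng.integers(2 ** 31)))
        for occ in occ_sets:
            model = EnsembleNicheModel(
                occ, env_model, families=tuple(mcfg["families"]),
                n_replicates=int(mcfg["n_replicates"]),
                train_frac=float(mcfg["train_frac"]),
                tss_min=float(mcfg["tss_min"]),
                seed=int(rng.integers(2 ** 31)), background=background)
            res = model.fit()
            ensembles[occ.species] = res
            br = res.binarize()
            ranges["current"][occ.species] = br
            areas["current"][occ.species] = br.area_km2
            for name, stack in scen_model.items():
                proj = res.project(stack, scenario=name)
                from .sdm import binarize as _binarize
                rb = _binarize(proj)
                ranges.setdefault(name, {})[occ.species] = rb
                areas.setdefault(name, {})[occ.species] = rb.area_km2
    except Exception as e:
        fail("fit", e)

    # -- overlap / breadth / identity statistics ----------------------
    try:
        rows = []
        species = [o.species for o in occ_sets]
        dists = {}
        for sp in species:
            dists[sp] = normalize(ensembles[sp].suitability, env_model.mask)
        breadth_rows = []
        for sp in species:
            b = levins_B(dists[sp])
            breadth_rows.append({"species": sp, "B_raw": b.B_raw,
                                 "B_std": b.B_std})
        it_cfg = cfg["identity_test"]
        occ_by_name = {o.species: o for o in occ_sets}
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                rec = {"species_a": a, "species_b": b,
                       "D": schoener_D(dists[a], dists[b]),
                       "I": warren_I(dists[a], dists[b])}
                if it_cfg.get("enabled"):
                    it = identity_test(
                        occ_by_name[a], occ_by_name[b], env_model, background,
                        n_reps=int(it_cfg["n_reps"]),
                        model_family=it_cfg.get("model_family", "GLM"),
                        seed=int(rng.integers(2 ** 31)))
                    rec.update({"D_glm": it.D_obs, "I_glm": it.I_obs,
                                "p_D": it.p_D, "p_I": it.p_I,
                                "significant": it.significant_D})
                rows.append(rec)
        overlap_df = pd.DataFrame(rows)
        breadth_df = pd.DataFrame(breadth_rows)
    except Exception as e:
        fail("overlap", e)

    # -- RI matrices + report -----------------------------------------
    try:
        matrices = {name: isolation_matrix(r, name)
                    for name, r in ranges.items()}
        shifts = {name: isolation_shift_summary(matrices["current"], m)
                  for name, m in matrices.items() if name != "current"}
        areas_df = area_dynamics(areas, "current")
        manifest = {
            "seed": master_seed,
            "config_hash": config_hash(cfg),
            "species": species,
            "scenarios": list(scen_stacks),
            "retained_layers": list(retained),
            "n_members": {sp: ensembles[sp].ensemble.n_members
                          for sp in species},
            "cutoffs": {sp: ensembles[sp].cutoff for sp in species},
        }
    except Exception as e:
        fail("isolate", e)

    report = ScenarioReport(cfg, areas_df, matrices, shifts, overlap_df,
                            breadth_df, scr, manifest, ensembles)
    if outdir:
        _write_artifacts(report, ranges, env_model, outdir)
    return report


def _write_artifacts(report: ScenarioReport, ranges, env, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    report.areas.to_csv(outdir / "area_dynamics.csv", index=False)
    report.overlap.to_csv(outdir / "niche_overlap.csv", index=False)
    report.breadth.to_csv(outdir / "niche_breadth.csv", index=False)
    for name, m in report.matrices.items():
        m.ri.to_csv(outdir / f"ri_matrix_{name}.csv")
    for name, s in report.shifts.items():
        s.to_csv(outdir / f"ri_shift_{name}.csv", index=False)
    for scen, by_sp in ranges.items():
        for sp, br in by_sp.items():
            rio.write_ascii_grid(
                outdir / f"range_{scen}_{sp}.asc",
                br.presence.astype(float), np.ones_like(br.presence, bool),
                br.transform)
    for sp, res in report.ensembles.items():
        rio.write_ascii_grid(outdir / f"suitability_current_{sp}.asc",
                             np.nan_to_num(res.suitability),
                             res.ensemble.mask, res.ensemble.transform)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, default=str)
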