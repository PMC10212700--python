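"""Pairwise ecogeographic isolation from binarized ranges.

For an ordered species pair (A, B), with S the number of cells where
both are predicted present and U_A the number of cells suitable for A
but not B,

    RI(A|B) = 1 - S / (S + U_A)

ranges from 0 (A's entire habitat shared with B) to 1 (completely
separated).  The measure is asymmetric: RI(A|B) and RI(B|A) differ
whenever the two ranges differ in size.  RI is computed on cell counts;
an empty range leaves that species' RI undefined (NaN) with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdm import BinaryRange


@dataclass
class PairIsolation:
    ri_a: float
    ri_b: float
    S: int
    U_a: int
    U_b: int


def ri_ecogeo(range_a: BinaryRange, range_b: BinaryRange) -> PairIsolation:
    """RI = 1 - S/(S + U) for both directions of a co-registered pair."""
    if range_a.presence.shape != range_b.presence.shape or \
            not range_a.transform.matches(range_b.transform):
        raise ValueError("ranges are not co-registered")
    a, b = range_a.presence, range_b.presence
    S = int(np.sum(a & b))
    u_a = int(np.sum(a & ~b))
    u_b = int(np.sum(b & ~a))
    ri_a = np.nan if S + u_a == 0 else 1.0 - S / (S + u_a)
    ri_b = np.nan if S + u_b == 0 else 1.0 - S / (S + u_b)
    return PairIsolation(float(ri_a), float(ri_b), S, u_a, u_b)


@dataclass
class IsolationMatrix:
    """RI for every ordered species pair under one scenario.

    ``ri.loc[A, B]`` is the isolation of A from B (the diagonal is NaN).
    """

    scenario: str
    species: list[str]
    ri: pd.DataFrame
    shared: pd.DataFrame
    unshared: pd.DataFrame  # unshared.loc[A, B] = U_A for pair (A, B)

    def ordered_pairs(self) -> pd.DataFrame:
        rows = []
        for a in self.species:
            for b in self.species:
                if a == b:
                    continue
                rows.append({"species": a, "partner": b,
                             "ri": self.ri.loc[a, b],
                             "S": self.shared.loc[a, b],
                             "U": self.unshared.loc[a, b],
                             "scenario": self.scenario})
        return pd.DataFrame(rows)

    def mean_ri(self) -> float:
        vals = self.ordered_pairs()["ri"].to_numpy()
        return float(np.nanmean(vals))


def isolation_matrix(ranges: dict[str, BinaryRange],
                     scenario: str = "current") -> IsolationMatrix:
    """All ordered-pair RI values for >= 2 species' ranges."""
    species = list(ranges)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    if len(set(species)) != len(species):
        raise ValueError("duplicated species label")
    ri = pd.DataFrame(np.nan, index=species, columns=species)
    shared = pd.DataFrame(0, index=species, columns=species)
    unshared = pd.DataFrame(0, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            pair = ri_ecogeo(ranges[a], ranges[b])
            ri.loc[a, b], ri.loc[b, a] = pair.ri_a, pair.ri_b
            shared.loc[a, b] = shared.loc[b, a] = pair.S
            unshared.loc[a, b], unshared.loc[b, a] = pair.U_a, pair.U_b
    return IsolationMatrix(scenario, species, ri, shared, unshared)


def area_dynamics(areas: dict[str, dict[str, float]],
                  current: str = "current") -> pd.DataFrame:
    """Habitat-area table: per species per scenario, area in 1e5 km^2 and
    the signed change vs the current scenario, formatted to 2 decimals.

    ``areas[scenario][species]`` is in km^2.
    """
    if current not in areas:
        raise ValueError(f"current scenario '{current}' missing")
    rows = []
    for sp in areas[current]:
        cur = areas[current][sp] / 1e5
        for scen, table in areas.items():
            a = table[sp] / 1e5
            delta = a - cur
            rows.append({
                "species": sp, "scenario": scen,
                "area_1e5_km2": round(a, 2),
                "delta_1e5_km2": round(delta, 2),
                "formatted": f"{a:.2f}" if scen == current
                else f"{a:.2f} [{delta:+.2f}]",
            })
    return pd.DataFrame(rows)


def isolation_shift_summary(current: IsolationMatrix,
                            scenario: IsolationMatrix) -> pd.DataFrame:
    """Per ordered pair, RI(scenario) - RI(current), with the mean shift.

    'above'/'on'/'below' classifies each pair against the identity line
    of a current-vs-scenario scatter.  The mean averages ordered pairs.
    """
    if set(current.species) != set(scenario.species):
        raise ValueError("species sets differ between matrices")
    cur = current.ordered_pairs().set_index(["species", "partner"])
    sce = scenario.ordered_pairs().set_index(["species", "partner"])
    out = pd.DataFrame({
        "ri_current": cur["ri"],
        "ri_scenario": sce["ri"],
    })
    out["delta"] = out["ri_scenario"] - out["ri_current"]
    out["position"] = np.select(
        [out["delta"] > 0, out["delta"] < 0], ["above", "below"], "on")
    out.attrs["mean_shift"] = float(np.nanmean(out["delta"]))
    out.attrs["scenario"] = scenario.scenario
    return out.reset_index()
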