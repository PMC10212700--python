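"""Replicate SDM fitting, ROC/TSS evaluation, ensembling, areas, projection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecogeo as eg
from ecogeo.sdm import EnsembleSuitability, TSS_MIN_DEFAULT


def _brute_auc(p, b):
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in p for y in b)
    return wins / (len(p) * len(b))


def _brute_tss(p, b):
    best = (-np.inf, None)
    for t in sorted(set(p) | set(b)):
        tss = np.mean(np.array(p) >= t) + np.mean(np.array(b) < t) - 1
        if tss > best[0] + 1e-15:
            best = (tss, t)
    return best


class TestEvaluate:
    def test_worked_example(self):
        m = eg.evaluate_scores([0.9, 0.8, 0.4], [0.7, 0.3, 0.2])
        assert m.auc == pytest.approx(8 / 9)
        assert m.tss_max == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        m = eg.evaluate_scores([0.9, 0.8], [0.2, 0.1])
        assert m.auc == 1.0 and m.tss_max == 1.0

    def test_constant_scores_uninformative(self):
        m = eg.evaluate_scores([0.5, 0.5], [0.5, 0.5])
        assert m.auc == 0.5 and m.tss_max == 0.0

    def test_rank_auc_matches_brute_force_and_trapezoid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_p = rng.integers(2, 25)
            n_b = rng.integers(2, 25)
            p = np.round(rng.random(n_p), 2)  # rounding induces ties
            b = np.round(rng.random(n_b), 2)
            auc = eg.auc_rank(p, b)
            assert auc == pytest.approx(_brute_auc(list(p), list(b)),
                                        abs=1e-10)
            # trapezoidal ROC integration oracle
            y = np.r_[np.ones(n_p), np.zeros(n_b)]
            s = np.r_[p, b]
            order = np.argsort(-s, kind="stable")
            fpr, tpr = [0.0], [0.0]
            tp = fp = 0
            for t in np.unique(s)[::-1]:
                tp = np.sum((s >= t) & (y == 1))
                fp = np.sum((s >= t) & (y == 0))
                tpr.append(tp / n_p)
                fpr.append(fp / n_b)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    def test_tss_scan_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = np.round(rng.random(rng.integers(2, 25)), 2)
            b = np.round(rng.random(rng.integers(2, 25)), 2)
            tss, thr = eg.tss_scan(p, b)
            b_tss, b_thr = _brute_tss(list(p), list(b))
            assert tss == pytest.approx(b_tss, abs=1e-10)
            assert thr == pytest.approx(b_thr)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            eg.evaluate_scores([], [0.1])


class TestBackgroundAndSplit:
    def test_background_on_valid_cells(self, tiny_env):
        occ = eg.sample_background(tiny_env, 500, seed=0)
        for lon, lat in occ.points:
            cell = tiny_env.cell_of(lon, lat)
            assert cell is not None and tiny_env.mask[cell]

    def test_background_deterministic(self, env_small):
        a = eg.sample_background(env_small, 100, seed=3)
        b = eg.sample_background(env_small, 100, seed=3)
        np.testing.assert_array_equal(a.points, b.points)

    def test_background_uniformity(self, tiny_env):
        n_valid = int(tiny_env.mask.sum())
        n = 4 * n_valid * 50  # generous multiplicity for the chi-square
        occ = eg.sample_background(tiny_env, n, seed=5)
        counts = np.zeros(n_valid)
        flat = {c: i for i, c in enumerate(zip(*np.where(tiny_env.mask)))}
        for lon, lat in occ.points:
            counts[flat[tiny_env.cell_of(lon, lat)]] += 1
        stat = ((counts - n / n_valid) ** 2 / (n / n_valid)).sum()
        assert stats.chi2.sf(stat, df=n_valid - 1) > 0.01

    def test_split_sizes(self):
        (pt, pv), (bt, bv) = eg.split_data(10, 100, 0.7, seed=0)
        assert len(pt) == 7 and len(pv) == 3
        assert len(bt) == 70 and len(bv) == 30

    def test_split_partition(self):
        (pt, pv), _ = eg.split_data(23, 10, 0.7, seed=1)
        assert set(pt) | set(pv) == set(range(23))
        assert set(pt) & set(pv) == set()

    def test_split_seed_dependence(self):
        a, _ = eg.split_data(20, 20, 0.7, seed=1)
        b, _ = eg.split_data(20, 20, 0.7, seed=2)
        assert len(a[0]) == len(b[0])
        assert not np.array_equal(a[0], b[0])

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            eg.split_data(1, 100)


@pytest.fixture(scope="module")
def trained(env_small, specialist, background_small):
    suit = eg.true_suitability(env_small, specialist)
    occ = eg.sample_occurrences(suit, env_small, 100, seed=11)
    pt, _ = eg.extract_at_points(env_small, occ)
    bt, _ = eg.extract_at_points(env_small, background_small)
    return pt, bt


class TestFitReplicate:
    def test_glm_recovers_gaussian_niche(self, trained, env_small, specialist):
        pt, bt = trained
        fit = eg.fit_replicate("GLM", pt, bt, env=env_small)
        fs = fit.feature_spec
        j = fs.variables.index("bio1")
        p = len(fs.variables)
        coef = fit.params[1:]
        assert coef[p + j] < 0  # concave response in bio1
        opt = fs.means[j] - fs.sds[j] * coef[j] / (2 * coef[p + j])
        assert abs(opt - specialist.niche_center["bio1"]) < \
            0.5 * specialist.niche_breadth["bio1"]

    def test_shuffled_labels_auc_near_half(self, trained, env_small):
        pt, bt = trained
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pool = pd.concat([pt, bt], ignore_index=True)
            perm = rng.permutation(len(pool))
            fake_p = pool.iloc[perm[:len(pt)]]
            fake_b = pool.iloc[perm[len(pt):]]
            (pi, pv), (bi, bv) = eg.split_data(len(fake_p), len(fake_b),
                                               0.7, seed)
            fit = eg.fit_replicate("GLM", fake_p.iloc[pi], fake_b.iloc[bi],
                                   env=env_small)
            aucs.append(fit.evaluate(fake_p.iloc[pv], fake_b.iloc[bv]).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_deterministic_fit(self, trained, env_small):
        pt, bt = trained
        a = eg.fit_replicate("GLM", pt, bt, env=env_small)
        b = eg.fit_replicate("GLM", pt, bt, env=env_small)
        np.testing.assert_array_equal(a.params, b.params)

    @pytest.mark.parametrize("family", ["MAXENT_LIKE", "MARS_LIKE"])
    def test_other_families_discriminate(self, trained, env_small, family):
        pt, bt = trained
        (pi, pv), (bi, bv) = eg.split_data(len(pt), len(bt), 0.7, 2)
        fit = eg.fit_replicate(family, pt.iloc[pi], bt.iloc[bi], env=env_small)
        ev = fit.evaluate(pt.iloc[pv], bt.iloc[bv])
        assert ev.auc > 0.8
        grid = fit.predict_stack(env_small)
        assert np.nanmin(grid) >= 0 and np.nanmax(grid) <= 1

    def test_monotone_degradation_with_training_size(self, env_small,
                                                     specialist,
                                                     background_small):
        suit = eg.true_suitability(env_small, specialist)
        bt, _ = eg.extract_at_points(env_small, background_small)
        med = {}
        for n in (100, 10):
            aucs = []
            for seed in range(20):
                occ = eg.sample_occurrences(suit, env_small, n, seed=seed)
                pt, _ = eg.extract_at_points(env_small, occ)
                (pi, pv), (bi, bv) = eg.split_data(len(pt), len(bt), 0.7,
                                                   seed)
                fit = eg.fit_replicate("GLM", pt.iloc[pi], bt.iloc[bi],
                                       env=env_small)
                aucs.append(fit.evaluate(pt.iloc[pv], bt.iloc[bv]).auc)
            med[n] = np.median(aucs)
        assert med[10] <= med[100]


class TestEnsemble:
    def _member(self, grid, tss, thr, env):
        class _Fake:
            pass
        m = _Fake()
        m.eval = eg.EvalMetrics(0.9, tss, thr)
        m.predict_stack = lambda e, g=grid: g
        m.feature_spec = None
        return m

    def test_identical_members_idempotent(self, tiny_env):
        g = np.random.default_rng(0).random(tiny_env.shape)
        fits = [self._member(g, 0.85, 0.4, tiny_env) for _ in range(3)]
        ens = eg.ensemble(fits, tiny_env)
        np.testing.assert_allclose(ens.suitability, g)
        assert ens.cutoff == pytest.approx(0.4)

    def test_weighted_mean_oracle(self, tiny_env):
        rng = np.random.default_rng(1)
        A, B = rng.random(tiny_env.shape), rng.random(tiny_env.shape)
        fits = [self._member(A, 0.9, 0.3, tiny_env),
                self._member(B, 0.8, 0.5, tiny_env)]
        ens = eg.ensemble(fits, tiny_env)
        np.testing.assert_allclose(ens.suitability, (0.9 * A + 0.8 * B) / 1.7)
        assert ens.cutoff == pytest.approx((0.9 * 0.3 + 0.8 * 0.5) / 1.7)

    def test_all_below_threshold_rejected(self, tiny_env):
        fits = [self._member(np.zeros(tiny_env.shape), 0.5, 0.3, tiny_env)]
        with pytest.raises(ValueError, match="no admissible"):
            eg.ensemble(fits, tiny_env)

    def test_ensemble_bounded_by_members(self, tiny_env):
        rng = np.random.default_rng(2)
        grids = [rng.random(tiny_env.shape) for _ in range(4)]
        fits = [self._member(g, 0.8 + 0.05 * i, 0.4, tiny_env)
                for i, g in enumerate(grids)]
        ens = eg.ensemble(fits, tiny_env)
        lo, hi = np.min(grids, axis=0), np.max(grids, axis=0)
        assert np.all(ens.suitability >= lo - 1e-12)
        assert np.all(ens.suitability <= hi + 1e-12)


class TestBinarizeAndArea:
    def _ens(self, suit, env, cutoff):
        return EnsembleSuitability(suit, env.mask, env.transform, 1,
                                   np.array([1.0]), cutoff)

    def test_low_cutoff_covers_positive_cells(self, tiny_env):
        suit = np.random.default_rng(0).random(tiny_env.shape)
        br = eg.binarize(self._ens(suit, tiny_env, 1e-9))
        np.testing.assert_array_equal(br.presence, tiny_env.mask)

    def test_high_cutoff_empty(self, tiny_env):
        suit = 0.3 * np.ones(tiny_env.shape)
        br = eg.binarize(self._ens(suit, tiny_env, 0.99))
        assert br.presence.sum() == 0 and br.area_km2 == 0

    def test_cutoff_override(self, tiny_env):
        suit = np.linspace(0, 1, 20).reshape(tiny_env.shape)
        br = eg.binarize(self._ens(suit, tiny_env, 0.2), cutoff=0.5)
        assert br.presence.sum() == ((suit >= 0.5) & tiny_env.mask).sum()

    def test_equatorial_cell_area(self):
        # one 2.5 arc-min cell centred on the equator: ~21.5 km^2
        cs = 2.5 / 60
        t = eg.GridTransform(0.0, -cs / 2, cs)
        area = eg.area_km2(np.ones((1, 1), bool), t)
        assert area == pytest.approx(21.5, rel=0.01)

    def test_high_latitude_cell_half_area(self):
        cs = 2.5 / 60
        eq = eg.area_km2(np.ones((1, 1), bool),
                         eg.GridTransform(0.0, -cs / 2, cs))
        hi = eg.area_km2(np.ones((1, 1), bool),
                         eg.GridTransform(0.0, 60.0 - cs / 2, cs))
        assert hi / eq == pytest.approx(np.cos(np.deg2rad(60)), rel=1e-3)

    def test_empty_range_zero_area(self, tiny_env):
        assert eg.area_km2(np.zeros(tiny_env.shape, bool),
                           tiny_env.transform) == 0.0


@pytest.fixture(scope="module")
def fitted(env_small, specialist, background_small):
    suit = eg.true_suitability(env_small, specialist)
    occ = eg.sample_occurrences(suit, env_small, 120, seed=21)
    model = eg.EnsembleNicheModel(occ, env_small, background=background_small,
                                  families=("GLM",), n_replicates=3,
                                  tss_min=0.5, seed=1)
    return model.fit()


class TestProjection:
    def test_projecting_onto_training_stack_is_identity(self, fitted,
                                                        env_small):
        proj = fitted.project(env_small, scenario="self")
        np.testing.assert_allclose(proj.suitability,
                                   fitted.ensemble.suitability,
                                   rtol=0, atol=1e-12)
        assert proj.cutoff == fitted.cutoff

    def test_uniform_shift_translates_optimum(self, fitted, env_small,
                                              specialist):
        shift = eg.ScenarioShift("warm", additive_offsets={"bio1": 3.0})
        scen = eg.apply_scenario(env_small, shift)
        proj = fitted.project(scen, scenario="warm")
        cur = fitted.ensemble.suitability
        old_opt = np.unravel_index(np.nanargmax(cur), cur.shape)
        # the old optimum cell's environment warmed past the niche centre
        assert proj.suitability[old_opt] < np.nanmax(proj.suitability) - 1e-6

    def test_missing_layer_rejected(self, fitted, env_small):
        partial = eg.EnvStack({"bio1": env_small.layers["bio1"]},
                              env_small.mask, env_small.transform)
        with pytest.raises(KeyError, match="missing"):
            fitted.project(partial)


class TestAverageScenarios:
    def test_self_average_identity(self, tiny_env):
        out = eg.average_scenarios([tiny_env, tiny_env])
        np.testing.assert_array_equal(out.layers["bio1"],
                                      tiny_env.layers["bio1"])

    def test_linearity(self, tiny_env):
        shifted = eg.apply_scenario(
            tiny_env, eg.ScenarioShift("s", additive_offsets={"bio1": 2.0}))
        out = eg.average_scenarios([tiny_env, shifted])
        m = tiny_env.mask
        np.testing.assert_allclose(out.layers["bio1"][m],
                                   tiny_env.layers["bio1"][m] + 1.0)

    def test_three_stack_mean_matches_loop(self, tiny_env):
        rng = np.random.default_rng(3)
        stacks = []
        for _ in range(3):
            s = tiny_env.copy()
            for k in s.layers:
                s.layers[k] = s.layers[k] + rng.random(s.shape)
                s.layers[k][~s.mask] = np.nan
            stacks.append(s)
        out = eg.average_scenarios(stacks)
        m = tiny_env.mask
        expect = sum(s.layers["bio12"][m] for s in stacks) / 3
        np.testing.assert_allclose(out.layers["bio12"][m], expect)

    def test_mismatched_stacks_rejected(self, tiny_env, env_small):
        from ecogeo.raster import CoRegistrationError
        with pytest.raises(CoRegistrationError):
            eg.average_scenarios([tiny_env, env_small])


def test_disjoint_niches_give_disjoint_ranges(env_small, background_small):
    """Two species with fully separated niches binarize to disjoint ranges
    (downstream RI = 1) in nearly all seeds."""
    ok = 0
    for seed in range(20):
        ranges = []
        for name, centre in (("a", 0.0), ("b", 16.0)):
            sp = eg.VirtualSpecies(name, {"bio1": centre}, {"bio1": 1.0})
            suit = eg.true_suitability(env_small, sp)
            occ = eg.sample_occurrences(suit, env_small, 80, seed=seed)
            model = eg.EnsembleNicheModel(occ, env_small,
                                          background=background_small,
                                          families=("GLM",), n_replicates=2,
                                          tss_min=0.5, seed=seed)
            ranges.append(model.fit().binarize())
        pair = eg.ri_ecogeo(*ranges)
        if pair.ri_a == 1.0 and pair.ri_b == 1.0:
            ok += 1
    assert ok >= 19
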