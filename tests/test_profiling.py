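"""Layer/ROI profiling, the ANOVAs, and the post-hoc battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shapecat as sc
from shapecat.exceptions import InsufficientDataError, ValidationError
from shapecat.profiling import AnovaEffect, layer_trend_roi_anova

from conftest import random_rdm


def _profile_from_series(rho_shape, rho_category):
    L = len(rho_shape)
    flags = np.zeros(L, dtype=bool)
    thr = np.zeros(L)
    return sc.LayerProfile(
        network_tag="t", layer_index=tuple(range(L)),
        rho_shape=np.asarray(rho_shape, float),
        rho_category=np.asarray(rho_category, float),
        significant_shape=flags, significant_category=flags,
        threshold_shape=thr, threshold_category=thr, method="plain")


class TestLayerProfile:
    def test_layer_equal_to_shape_model_has_rho_one(self, design_2x2):
        m_s = sc.model_rdm(design_2x2, "shape")
        m_c = sc.model_rdm(design_2x2, "category")
        prof = sc.layer_profile([m_s], m_s, m_c, n_perm=50, seed=0,
                                partial_when_dependent=False)
        assert prof.rho_shape[0] == pytest.approx(1.0)

    def test_noiseless_monotone_schedules_are_recovered(self, design_2x2):
        spec = sc.SynthSpec(noise_sd=0.0, seed=21)
        rdms = [sc.compute_rdm(pm)
                for pm in sc.make_layer_activations(design_2x2, spec)]
        m_s = sc.model_rdm(design_2x2, "shape")
        m_c = sc.model_rdm(design_2x2, "category")
        prof = sc.layer_profile(rdms, m_s, m_c, n_perm=50, seed=1)
        assert stats.spearmanr(prof.rho_category,
                               spec.category_schedule).statistic == 1.0
        assert stats.spearmanr(prof.rho_shape,
                               spec.shape_schedule).statistic == 1.0
        assert prof.argmax_layer("category") == prof.layer_index[-1]

    def test_shuffled_design_yields_mostly_nonsignificant_profiles(self, design_2x2):
        # null calibration: destroying the label structure before model
        # construction should leave ≥ 90% of layer flags non-significant
        master = np.random.default_rng(7)
        total = flagged = 0
        for _ in range(25):
            seed = int(master.integers(2 ** 31))
            rng = np.random.default_rng(seed)
            perm = rng.permutation(design_2x2.n_conditions)
            shuffled = sc.StimulusDesign(
                design_2x2.condition_ids,
                [design_2x2.shape_labels[i] for i in perm],
                [design_2x2.category_labels[i] for i in perm])
            spec = sc.SynthSpec(seed=seed)
            rdms = [sc.compute_rdm(pm)
                    for pm in sc.make_layer_activations(design_2x2, spec)]
            prof = sc.layer_profile(rdms, sc.model_rdm(shuffled, "shape"),
                                    sc.model_rdm(shuffled, "category"),
                                    n_perm=99, seed=seed)
            flagged += int(prof.significant_shape.sum())
            flagged += int(prof.significant_category.sum())
            total += 2 * prof.n_layers
        assert flagged / total <= 0.10

    def test_duplicate_layer_indices_rejected(self, design_2x2):
        m_s = sc.model_rdm(design_2x2, "shape")
        m_c = sc.model_rdm(design_2x2, "category")
        with pytest.raises(ValidationError):
            sc.layer_profile([m_s, m_s], m_s, m_c, n_perm=10, seed=0,
                             layer_index=[1, 1])


class TestLayerConditionAnova:
    def test_identical_series_zero_condition_and_interaction(self):
        rho = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        table = sc.layer_condition_anova(_profile_from_series(rho, rho))
        assert table["Condition"].F == pytest.approx(0.0, abs=1e-10)
        assert table["Interaction"].F == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_explicit_nested_rss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 12))
        x = np.arange(L, dtype=float)
        rho_s = 0.5 - 0.02 * x + 0.1 * rng.standard_normal(L)
        rho_c = 0.1 + 0.05 * x + 0.1 * rng.standard_normal(L)
        table = sc.layer_condition_anova(_profile_from_series(rho_s, rho_c))
        # independent oracle: statsmodels OLS on the same model matrix,
        # F from the nested residual sums of squares
        import statsmodels.api as sm

        xc = np.concatenate([x, x]) - x.mean()
        cond = np.concatenate([np.full(L, 0.5), np.full(L, -0.5)])
        y = np.concatenate([rho_s, rho_c])
        X = np.column_stack([np.ones(2 * L), xc, cond, xc * cond])
        full = sm.OLS(y, X).fit()
        for name, col in (("Layer", 1), ("Condition", 2), ("Interaction", 3)):
            red = sm.OLS(y, np.delete(X, col, axis=1)).fit()
            F = (red.ssr - full.ssr) / (full.ssr / (2 * L - 4))
            assert table[name].F == pytest.approx(F, abs=1e-8)
            assert table[name].df_den == 2 * L - 4

    def test_interaction_type_one_error_calibrated(self):
        # no planted interaction: rejection rate at alpha 0.05 within
        # 0.05 ± 0.02 over 500 simulations
        rng = np.random.default_rng(17)
        reject = 0
        reps = 500
        for _ in range(reps):
            L = 10
            x = np.arange(L, dtype=float)
            rho_s = 0.4 - 0.02 * x + 0.05 * rng.standard_normal(L)
            rho_c = 0.1 - 0.02 * x + 0.05 * rng.standard_normal(L)
            table = sc.layer_condition_anova(_profile_from_series(rho_s, rho_c))
            reject += table["Interaction"].p_value < 0.05
        assert 0.03 <= reject / reps <= 0.07

    def test_f_invariant_to_shift_and_scale(self):
        rng = np.random.default_rng(3)
        rho_s = rng.random(6)
        rho_c = rng.random(6)
        t1 = sc.layer_condition_anova(_profile_from_series(rho_s, rho_c))
        t2 = sc.layer_condition_anova(
            _profile_from_series(3.0 * rho_s + 0.7, 3.0 * rho_c + 0.7))
        for name in ("Layer", "Condition", "Interaction"):
            assert t2[name].F == pytest.approx(t1[name].F, rel=1e-9)

    def test_too_few_layers_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.layer_condition_anova(_profile_from_series([0.1, 0.2], [0.3, 0.4]))


def _grid_profile(vals):
    n, q, p = vals.shape
    return sc.SubjectRoiProfile(tuple(f"s{i}" for i in range(n)),
                                tuple(f"r{i}" for i in range(q)),
                                tuple(["shape", "category"][:p]), vals)


class TestRoiConditionAnova:
    def test_constant_data_gives_zero_f(self):
        table = sc.roi_condition_anova(_grid_profile(np.full((4, 3, 2), 0.3)))
        for e in table.effects:
            assert e.F == 0.0 and e.p_value == 1.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_anova_rm_oracle(self, seed):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(seed + 7)
        n = int(rng.integers(3, 7))
        vals = rng.standard_normal((n, 3, 2))
        table = sc.roi_condition_anova(_grid_profile(vals))
        rows = [{"subject": s, "roi": f"r{r}", "cond": c,
                 "y": vals[s, r, ci]}
                for s in range(n) for r in range(3)
                for ci, c in enumerate(("shape", "category"))]
        oracle = AnovaRM(pd.DataFrame(rows), "y", "subject",
                         within=["cond", "roi"]).fit().anova_table
        assert table["Condition"].F == pytest.approx(
            oracle.loc["cond", "F Value"], abs=1e-8)
        assert table["ROI"].F == pytest.approx(
            oracle.loc["roi", "F Value"], abs=1e-8)
        assert table["Interaction"].F == pytest.approx(
            oracle.loc["cond:roi", "F Value"], abs=1e-8)

    def test_small_grid_matches_hand_partitioned_ss(self):
        # 3-subject worked grid: sums of squares recomputed from cell and
        # marginal means, fully independently
        vals = np.array([
            [[0.3, 0.1], [0.2, 0.2], [0.1, 0.4]],
            [[0.4, 0.0], [0.3, 0.3], [0.0, 0.5]],
            [[0.2, 0.2], [0.1, 0.3], [0.2, 0.6]],
        ])
        n, q, p = vals.shape
        table = sc.roi_condition_anova(_grid_profile(vals))
        gm = vals.mean()
        mc = vals.mean(axis=(0, 1))
        ss_c = n * q * np.sum((mc - gm) ** 2)
        msc = vals.mean(axis=1)
        ms = vals.mean(axis=(1, 2))
        ss_cs = q * np.sum((msc - ms[:, None] - mc[None, :] + gm) ** 2)
        F_expected = (ss_c / (p - 1)) / (ss_cs / ((p - 1) * (n - 1)))
        assert table["Condition"].F == pytest.approx(F_expected, abs=1e-10)

    def test_planted_crossing_interaction_detected(self, design_2x2):
        # shape dominant in one ROI, category in another: the ROI × Condition
        # interaction should be overwhelmingly significant
        hits = 0
        seeds = 40
        for seed in range(seeds):
            spec = sc.SynthSpec(
                roi_weights=(("A", 1.0, 0.0), ("B", 0.5, 0.5), ("C", 0.0, 1.0)),
                n_subjects=8, seed=seed)
            grid = sc.make_subject_patterns(design_2x2, spec)
            m_s = sc.model_rdm(design_2x2, "shape")
            m_c = sc.model_rdm(design_2x2, "category")
            subs = tuple(grid)
            rois = ("A", "B", "C")
            vals = np.empty((len(subs), 3, 2))
            for si, s in enumerate(subs):
                for ri, r in enumerate(rois):
                    rdm = sc.compute_rdm(grid[s][r])
                    vals[si, ri, 0] = sc.spearman_rdm(rdm, m_s).rho
                    vals[si, ri, 1] = sc.spearman_rdm(rdm, m_c).rho
            table = sc.roi_condition_anova(
                sc.SubjectRoiProfile(subs, rois, ("shape", "category"), vals))
            hits += table["Interaction"].p_value < 0.001
        assert hits / seeds >= 0.95

    def test_incomplete_grid_rejected(self):
        vals = np.full((4, 3, 2), 0.1)
        vals[1, 2, 0] = np.nan
        with pytest.raises(ValidationError):
            _grid_profile(vals)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.roi_condition_anova(_grid_profile(np.random.rand(2, 3, 2)))


class TestBrainLayerProfile:
    def _grid(self, design, spec):
        return {s: {r: sc.compute_rdm(pm) for r, pm in rois.items()}
                for s, rois in sc.make_subject_patterns(design, spec).items()}

    def test_planted_gradient_orders_peak_layers(self, design_2x2):
        spec = sc.SynthSpec.paper_like(seed=4)
        layer_rdms = [sc.compute_rdm(pm)
                      for pm in sc.make_layer_activations(design_2x2, spec)]
        res = sc.brain_layer_profile(self._grid(design_2x2, spec), layer_rdms)
        assert res.peak_layer["V1"] < res.peak_layer["VTC_ant"]
        assert res.anova is not None

    def test_single_subject_flags_sem_and_refuses_anova(self, design_2x2):
        spec = sc.SynthSpec(n_subjects=1, seed=0)
        layer_rdms = [sc.compute_rdm(pm)
                      for pm in sc.make_layer_activations(design_2x2, spec)]
        with pytest.warns(UserWarning, match="single subject"):
            res = sc.brain_layer_profile(self._grid(design_2x2, spec), layer_rdms)
        assert res.anova is None
        assert np.all(np.isnan(res.profile.sem()))

    def test_identical_layer_rdms_flatten_layer_effect(self, design_2x2, rng):
        spec = sc.SynthSpec(n_subjects=5, seed=3)
        one = sc.compute_rdm(sc.make_layer_activations(design_2x2, spec)[0])
        res = sc.brain_layer_profile(self._grid(design_2x2, spec), [one] * 6)
        assert res.anova["Layer"].F == pytest.approx(0.0, abs=1e-10)

    def test_trend_anova_layer_f_equals_slope_t_squared(self, rng):
        vals = rng.standard_normal((6, 3, 5))
        prof = sc.SubjectRoiProfile(tuple(f"s{i}" for i in range(6)),
                                    ("a", "b", "c"),
                                    tuple(f"l{i}" for i in range(5)), vals)
        table = layer_trend_roi_anova(prof)
        x = np.arange(5.0) - 2.0
        slopes = (vals @ x / (x @ x)).mean(axis=1)
        t = stats.ttest_1samp(slopes, 0.0)
        assert table["Layer"].F == pytest.approx(t.statistic ** 2, abs=1e-8)
        assert table["Layer"].p_value == pytest.approx(t.pvalue, abs=1e-8)

    def test_trend_anova_roi_effect_matches_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        vals = rng.standard_normal((5, 3, 4))
        prof = sc.SubjectRoiProfile(tuple(f"s{i}" for i in range(5)),
                                    ("a", "b", "c"),
                                    tuple(f"l{i}" for i in range(4)), vals)
        table = layer_trend_roi_anova(prof)
        means = vals.mean(axis=2)
        rows = [{"subject": s, "roi": r, "y": means[s, ri]}
                for s in range(5) for ri, r in enumerate("abc")]
        oracle = AnovaRM(pd.DataFrame(rows), "y", "subject",
                         within=["roi"]).fit().anova_table
        assert table["ROI"].F == pytest.approx(oracle.loc["roi", "F Value"],
                                               abs=1e-8)


class TestPartialledBrainLayer:
    def test_pure_category_brain_with_category_control_vanishes(self, design_2x2):
        # brain RDMs built purely from the category structure: partialling
        # the category model should leave ≈ 0 at every layer. A single
        # embedding draw leaves sizeable pair-level fluctuation (the draw is
        # shared across subjects), so the profile is averaged over seeds.
        m_c = sc.model_rdm(design_2x2, "category")
        profiles = []
        for seed in range(6):
            spec = sc.SynthSpec(
                roi_weights=(("pure_cat", 0.0, 1.0),), n_subjects=3,
                subject_noise_sd=0.02, seed=seed)
            layer_rdms = [sc.compute_rdm(pm)
                          for pm in sc.make_layer_activations(design_2x2, spec)]
            grid = {s: {r: sc.compute_rdm(pm) for r, pm in rois.items()}
                    for s, rois in sc.make_subject_patterns(design_2x2,
                                                            spec).items()}
            prof = sc.partialled_brain_layer_profile(grid, layer_rdms, m_c)
            profiles.append(prof.group_mean()[0])
        per_layer = np.mean(profiles, axis=0)
        assert np.all(np.abs(per_layer) < 0.1)

    def test_partial_tracks_planted_category_weight(self, design_2x2):
        # mixed brain signal, shape partialled out: the remaining profile
        # should track the planted category schedule across layers
        spec = sc.SynthSpec.paper_like(seed=11)
        layer_rdms = [sc.compute_rdm(pm)
                      for pm in sc.make_layer_activations(design_2x2, spec)]
        grid = {s: {r: sc.compute_rdm(pm) for r, pm in rois.items()}
                for s, rois in sc.make_subject_patterns(design_2x2, spec).items()}
        m_s = sc.model_rdm(design_2x2, "shape")
        prof = sc.partialled_brain_layer_profile(grid, layer_rdms, m_s)
        ant = list(prof.rois).index("VTC_ant")
        mean_ant = prof.group_mean()[ant]
        rc = stats.spearmanr(mean_ant, spec.category_schedule).statistic
        assert rc > 0.9


class TestPosthoc:
    def test_paired_t_identical_samples(self):
        res = sc.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_one_sample_t_matches_textbook_formula(self):
        x = [0.12, 0.31, 0.25, 0.18, 0.40]
        res = sc.one_sample_t(x)
        n = len(x)
        mean = sum(x) / n
        sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
        t_expected = mean / (sd / n ** 0.5)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.df == n - 1
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_expected), n - 1), abs=1e-12)

    def test_paired_t_matches_scipy(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        res = sc.paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_one_sample_power_matches_noncentral_t(self):
        # planted shift of 1 SD, n = 14: empirical rejection rate over 500
        # seeds should match the analytic noncentral-t power within ±0.05
        n = 14
        alpha = 0.05
        delta = np.sqrt(n) * 1.0
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = (1 - stats.nct.cdf(tcrit, n - 1, delta)
                 + stats.nct.cdf(-tcrit, n - 1, delta))
        rng = np.random.default_rng(23)
        rej = sum(
            sc.one_sample_t(rng.standard_normal(n) + 1.0).p_value < alpha
            for _ in range(500)) / 500
        assert abs(rej - power) < 0.05

    def test_tukey_q_matches_textbook_formula(self, rng):
        vals = rng.standard_normal((6, 3)) + np.array([0.0, 0.5, 1.0])
        results = sc.tukey_hsd_rm(vals, ["a", "b", "c"])
        n, k = vals.shape
        m = vals.mean()
        ml = vals.mean(axis=0)
        msub = vals.mean(axis=1)
        ss_err = np.sum((vals - ml[None, :] - msub[:, None] + m) ** 2)
        ms_err = ss_err / ((k - 1) * (n - 1))
        q01 = abs(ml[0] - ml[1]) / np.sqrt(ms_err / n)
        first = results[0]
        assert first.statistic == pytest.approx(q01, abs=1e-10)
        assert first.p_value == pytest.approx(
            stats.studentized_range.sf(q01, k, (k - 1) * (n - 1)), abs=1e-10)

    def test_posthoc_dispatcher(self, rng):
        vals = rng.standard_normal((5, 3, 2))
        prof = _grid_profile(vals)
        out = sc.posthoc_tests(prof, [
            ("paired_t", "r0", "shape", "category"),
            ("one_sample_t", "r2", "category"),
            ("tukey_rois",),
        ])
        names = [t.name for t in out]
        assert names[0].startswith("paired_t:r0")
        assert names[1].startswith("one_sample_t:r2")
        assert len(out) == 2 + 3  # 3 pairwise Tukey comparisons

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            sc.one_sample_t([0.5])
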