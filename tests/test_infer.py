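"""Estimation toolkit: transforms, decay fits, SMA, jackknife, model choice."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polyhybrid as ph
from polyhybrid import infer


class TestBoxCox:
    def test_identity_at_lambda_one(self):
        x = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(infer.boxcox(x, 1.0), x - 1)

    def test_log_at_lambda_zero(self):
        x = np.array([1.0, np.e, np.e**2])
        np.testing.assert_allclose(infer.boxcox(x, 0.0), [0, 1, 2])

    def test_square_root_case(self):
        assert infer.boxcox(np.array([4.0]), 0.5)[0] == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            infer.boxcox(np.array([1.0, 0.0]), 0.5)

    def test_shift_rule(self):
        x = np.array([-3.0, 0.0, 7.0])
        s = infer.shift_positive(x)
        assert (x + s).min() == pytest.approx(0.01 * 10.0)
        assert infer.shift_positive(np.array([0.5, 1.0])) == 0.0


class TestChooseLambdaSkewmin:
    def test_symmetric_groups_pick_identity(self):
        groups = [np.array([1.0, 2.0, 3.0]) + k for k in range(4)]
        spec = infer.choose_lambda_skewmin(groups)
        assert spec.lam == pytest.approx(1.0, abs=0.02)

    def test_lognormal_groups_pick_log(self, rng):
        groups = [np.exp(rng.normal(1.0, 0.6, size=400)) for _ in range(5)]
        spec = infer.choose_lambda_skewmin(groups)
        assert abs(spec.lam) < 0.15

    def test_argmin_property(self, rng):
        groups = [rng.gamma(2.0, 1.0, size=30) for _ in range(3)]
        spec = infer.choose_lambda_skewmin(groups)
        shift = spec.shift
        for lam in (-1.0, 0.0, 0.5, 1.0, 2.0):
            obj = sum(
                infer._safe_skew(infer.boxcox(g + shift, lam)) ** 2 for g in groups
            )
            assert spec.score <= obj + 1e-12

    def test_degenerate_groups_tie_break_to_identity(self):
        groups = [np.array([2.0, 2.0]), np.array([5.0, 5.0, 5.0])]
        assert infer.choose_lambda_skewmin(groups).lam == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            infer.choose_lambda_skewmin([np.array([1.0])])


class TestChooseLambdaSMA:
    def test_exact_equality_tie_breaks_to_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        spec = infer.choose_lambda_sma(x, x.copy())
        assert spec.lam == 1.0 and spec.score == pytest.approx(1.0)

    def test_power_law_linearized_by_log(self, rng):
        x = np.exp(rng.normal(2.0, 0.5, size=40))
        y = 2.0 * x**1.7 * np.exp(rng.normal(0, 0.01, size=40))
        spec = infer.choose_lambda_sma(x, y)
        assert abs(spec.lam) <= 0.1

    def test_argmax_property(self, rng):
        x = rng.uniform(1, 10, size=15)
        y = x + rng.normal(0, 0.5, size=15)
        spec = infer.choose_lambda_sma(x, y)
        for lam in (-2.0, -0.5, 0.0, 1.0, 2.0):
            tx = infer.boxcox(x + spec.shift, lam)
            ty = infer.boxcox(y + spec.shift, lam)
            assert spec.score >= np.corrcoef(tx, ty)[0, 1] ** 2 - 1e-12

    def test_incomplete_pairs_excluded_and_counted(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        y = np.array([1.1, 2.2, 3.0, 4.4])
        assert infer.choose_lambda_sma(x, y).lam is not None
        with pytest.raises(ValueError, match="3 complete pairs"):
            infer.choose_lambda_sma(x[:3], y[:3])


def decay_table(K, m_by_cross, gens=(0, 1, 3, 5, 7), reps=3, noise=0.0, rng=None):
    beta = float(ph.beta_retention(K))
    rows = []
    for cross, m in m_by_cross.items():
        for t in gens:
            mu = (beta**t - 1) * m / 4
            for r in range(reps):
                v = mu if rng is None else mu + rng.normal(0, noise)
                rows.append((cross, K, t, r + 1, v))
    return pd.DataFrame(
        rows, columns=["cross", "ploidy", "generation", "replicate", "value"]
    )


class TestSelfingDecay:
    @pytest.mark.parametrize("K", [2, 4])
    def test_noiseless_recovery_exact(self, K):
        data = decay_table(K, {"A×B": 2.0})
        m = infer.fit_selfing_decay(data, ploidy=K)
        assert m.beta_ == pytest.approx(float(ph.beta_retention(K)), rel=1e-6)
        assert m.amplitudes_["A×B"] == pytest.approx(2.0 / 4, rel=1e-6)
        assert m.baselines_["A×B"] == pytest.approx(0.0, abs=1e-9)

    def test_pooled_fit_one_beta_two_amplitudes(self):
        data = decay_table(4, {"A×B": 2.0, "C×D": 1.6})
        m = infer.fit_selfing_decay(data, ploidy=4)
        assert len(m.amplitudes_) == 2
        assert m.amplitudes_["C×D"] == pytest.approx(0.4, rel=1e-6)

    def test_fixed_beta_fits_amplitudes_only(self):
        data = decay_table(2, {"A×B": 1.0})
        m = infer.fit_selfing_decay(data, ploidy=2, fix_beta="ploidy")
        assert m.beta_ == 0.5 and m.beta_ci_ == (0.5, 0.5)
        assert m.amplitudes_["A×B"] == pytest.approx(0.25, rel=1e-9)

    def test_affine_invariance(self, rng):
        data = decay_table(4, {"A×B": 2.0}, noise=0.05, rng=rng)
        m0 = infer.fit_selfing_decay(data, ploidy=4)
        scaled = data.assign(value=3.0 * data["value"] + 11.0)
        m1 = infer.fit_selfing_decay(scaled, ploidy=4)
        assert m1.beta_ == pytest.approx(m0.beta_, abs=1e-7)
        assert m1.amplitudes_["A×B"] == pytest.approx(3.0 * m0.amplitudes_["A×B"], rel=1e-6)

    def test_ci_covers_truth_on_noisy_data(self, rng):
        data = decay_table(4, {"A×B": 2.0}, reps=5, noise=0.02, rng=rng)
        m = infer.fit_selfing_decay(data, ploidy=4)
        lo, hi = m.beta_ci_
        assert lo < 5 / 6 < hi and lo < hi

    def test_single_generation_rejected(self):
        data = decay_table(2, {"A×B": 1.0}, gens=(3,))
        with pytest.raises(ValueError, match="distinct generations"):
            infer.fit_selfing_decay(data)

    def test_predict_reproduces_fitted_means(self):
        data = decay_table(2, {"A×B": 1.0})
        m = infer.fit_selfing_decay(data, ploidy=2)
        np.testing.assert_allclose(m.predict(data), data["value"], atol=1e-8)

    def test_sklearn_param_interface(self):
        m = infer.SelfingDecayModel(ploidy=4)
        assert m.get_params()["ploidy"] == 4
        m.set_params(fix_beta=0.5)
        assert m.fix_beta == 0.5


class TestPloidyScan:
    @pytest.mark.parametrize("K", [2, 4])
    def test_noiseless_argmax_with_clear_gap(self, K):
        data = decay_table(K, {"A×B": 2.0, "C×D": 1.6})
        scan = infer.ploidy_scan(data)
        assert scan.best_ploidy == K
        logliks = scan.table.set_index("ploidy")["loglik"]
        rivals = logliks.drop(K)
        assert logliks[K] - rivals.max() >= 2.0

    def test_noisy_seeded_scan(self, rng):
        data = decay_table(4, {"A×B": 2.0}, reps=5, noise=0.02, rng=rng)
        assert infer.ploidy_scan(data).best_ploidy == 4


class TestHeterozygoteClasses:
    @staticmethod
    def class_table(M=2.0, gens=(0, 1, 3, 5, 7), reps=3, noise=0.0, rng=None,
                    unbalanced_zeroed=False):
        rows = []
        for t in gens:
            p = ph.tetraploid_class_probs(t)
            mu = (float(p.pr_balanced) - 1) * M / 4
            if not unbalanced_zeroed:
                mu += float(p.pr_unbalanced) * 3 * M / 16
            for r in range(reps):
                v = mu if rng is None else mu + rng.normal(0, noise)
                rows.append(("A×B", 4, t, r + 1, v))
        return pd.DataFrame(
            rows, columns=["cross", "ploidy", "generation", "replicate", "value"]
        )

    def test_noiseless_ratio_is_three_quarters(self):
        m = infer.fit_het_classes(self.class_table())
        assert m.ratio_ == pytest.approx(0.75, rel=1e-9)
        assert m.b22_ == pytest.approx(0.5, rel=1e-9)

    def test_unbalanced_term_zeroed(self):
        m = infer.fit_het_classes(self.class_table(unbalanced_zeroed=True))
        assert m.b13_ == pytest.approx(0.0, abs=1e-10)
        assert m.ratio_ == pytest.approx(0.0, abs=1e-9)

    def test_ci_covers_truth_on_noisy_data(self, rng):
        m = infer.fit_het_classes(self.class_table(reps=5, noise=0.02, rng=rng))
        lo, hi = m.ratio_ci_
        assert lo < 0.75 < hi

    def test_collinear_generations_flagged(self):
        with pytest.raises(ValueError, match="collinear"):
            infer.fit_het_classes(self.class_table(gens=(0, 1)))

    def test_near_zero_balanced_coefficient_flagged(self):
        data = self.class_table(M=0.0)
        m = infer.fit_het_classes(data)
        assert not m.ratio_defined_
        assert np.isnan(m.ratio_)


class TestSMA:
    def test_perfect_identity(self):
        m = infer.sma_fit(np.arange(5.0), np.arange(5.0))
        assert (m.slope_, m.intercept_) == (1.0, 0.0)
        assert m.r2_ == pytest.approx(1.0)

    def test_exact_affine(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        m = infer.sma_fit(x, 2 * x + 1)
        assert m.slope_ == pytest.approx(2.0)
        assert m.intercept_ == pytest.approx(1.0)

    @settings(derandomize=True)
    @given(st.integers(0, 1000))
    def test_slope_magnitude_is_sd_ratio_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 2, size=12)
        y = 0.5 * x + r.normal(0, 1, size=12)
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            return
        m = infer.sma_fit(x, y)
        assert abs(m.slope_) == pytest.approx(y.std(ddof=1) / x.std(ddof=1))
        back = infer.sma_fit(y, x)
        assert back.slope_ == pytest.approx(1 / m.slope_)
        assert back.r2_ == pytest.approx(m.r2_)

    def test_imputation_on_line(self):
        m = infer.sma_fit(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert infer.sma_impute(m, np.array([10.0]))[0] == pytest.approx(20.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            infer.sma_fit(np.ones(4), np.arange(4.0))


class TestHeterosisTable:
    def test_zero_noise_contrasts(self, noiseless_rye):
        t = infer.heterosis_table(noiseless_rye)
        inc = t[t["predicted"] == 0.25]
        assert len(inc) == 4  # two increments x two ploidies
        np.testing.assert_allclose(inc["value"], 0.25, atol=1e-12)
        f1 = t[(t["contrast"] == "F1-Par") & (t["ploidy"] == 2)]
        assert f1["value"].iloc[0] == pytest.approx(1.0)

    def test_missing_cohort_flagged(self, noiseless_rye):
        sub = noiseless_rye[noiseless_rye["P"] != 4]
        t = infer.heterosis_table(sub)
        gone = t[t["contrast"] == "F2[4]-F2[3]"]
        assert gone["missing"].all() and gone["value"].isna().all()

    def test_zero_denominator_rejected(self, noiseless_rye):
        flat = noiseless_rye.copy()
        flat["value"] = 1.0
        with pytest.raises(ValueError, match="normalize"):
            infer.heterosis_table(flat)


class TestJackknife:
    def test_constant_statistic_zero_spread(self, noiseless_rye):
        jk = infer.jackknife(noiseless_rye, lambda d: 1.25, "leave-line")
        assert (jk.values["stat"] == 1.25).all()
        assert jk.se["stat"] == pytest.approx(0.0)
        assert jk.spread["stat"] == 0.0

    def test_resample_counts(self, noiseless_rye):
        assert len(infer.jackknife(noiseless_rye, lambda d: 0.0, "leave-line").values) == 6
        assert len(infer.jackknife(noiseless_rye, lambda d: 0.0, "leave-pair").values) == 15

    def test_leave_line_removes_every_cross_naming_the_line(self, noiseless_rye):
        seen = {}
        infer.jackknife(
            noiseless_rye,
            lambda d: seen.setdefault(len(seen), set(d["cross"])) and 0.0,
            "leave-line",
        )
        removed_A = set(noiseless_rye["cross"]) - seen[0]
        assert all("A" in ph.parse_cross(s).lines for s in removed_A)
        assert not any("A" in ph.parse_cross(s).lines for s in seen[0])

    def test_line_schemes_cover_every_nonparental_cross_twice(self, noiseless_rye):
        # each cross names >= 2 lines, so the union over line-deletions
        # removes it at least twice
        all_crosses = set(noiseless_rye["cross"])
        removal_counts = {s: 0 for s in all_crosses}
        lines = sorted({l for s in all_crosses for l in ph.parse_cross(s).lines})
        for line in lines:
            for s in all_crosses:
                if line in ph.parse_cross(s).lines:
                    removal_counts[s] += 1
        for s, n in removal_counts.items():
            if ph.parse_cross(s).kind != "parent":
                assert n >= 2, s

    def test_failing_resample_flagged_not_dropped(self, noiseless_rye):
        def bad(d):
            if "A" not in set().union(*(ph.parse_cross(s).lines for s in d["cross"])):
                raise RuntimeError("statistic undefined without line A")
            return 0.0

        jk = infer.jackknife(noiseless_rye, bad, "leave-line")
        assert [label for label, _ in jk.failed] == ["A"]
        assert len(jk.values) == 5

    def test_unknown_scheme_rejected(self, noiseless_rye):
        with pytest.raises(ValueError, match="scheme"):
            infer.jackknife(noiseless_rye, lambda d: 0.0, "bootstrap")


class TestSelectRyeModel:
    @staticmethod
    def panel(cost=0.0, maternal=0.0):
        design = dataclasses.replace(
            ph.RyeDesign(),
            noise_sd=0.0,
            drop_missing_f1=False,
            ploidy_cost=cost,
            maternal_boost=maternal,
        )
        return ph.gen_rye_dataset(design)

    def test_zero_offsets_prefer_base(self):
        assert infer.select_rye_model(self.panel()).best == "base"

    def test_maternal_offset_detected(self):
        sel = infer.select_rye_model(self.panel(maternal=0.3))
        assert sel.best == "maternal"
        assert sel.coefficients["maternal"] == pytest.approx(0.3, abs=1e-9)

    def test_cost_plus_maternal_beats_free_slope_by_parsimony(self):
        sel = infer.select_rye_model(self.panel(cost=-0.5, maternal=0.3))
        assert sel.best == "cost+maternal"
        assert sel.coefficients["ploidy_cost"] == pytest.approx(-0.5, abs=1e-9)
        aic = sel.table.set_index("model")["aic"]
        assert aic["cost+maternal"] < aic["cost+maternal+free-slope"]

    def test_recovers_generating_genetic_parameters(self):
        sel = infer.select_rye_model(self.panel(cost=-0.5, maternal=0.3))
        d = ph.RyeDesign()
        assert sel.coefficients["Mbar"] == pytest.approx(d.mbar, abs=1e-8)
        assert sel.coefficients["Ibar"] == pytest.approx(d.ibar, abs=1e-8)
        for i, l in enumerate(d.lines):
            assert sel.coefficients[f"W[{l}]"] == pytest.approx(d.w[i], abs=1e-8)
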