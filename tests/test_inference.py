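"""TANOVA, split-plot ANOVA, follow-ups, and moderation regression."""
import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import microdyn as md
from microdyn.containers import demean
from microdyn.inference import followup_oneway, mixed_anova, moderation_analysis


def anova_long(n_per=6, effect=0.0, class_effects=(0.0, 1.0, 2.0, 3.0), sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per):
        g = "treatment" if i < n_per else "placebo"
        for j, c in enumerate("ABCD"):
            rows.append(dict(
                subject_id=f"S{i:02d}", group=g, level=c,
                value=rng.normal(75 + (effect if g == "treatment" else 0)
                                 + class_effects[j], sd),
            ))
    return pd.DataFrame(rows)


class TestTanova:
    def _maps(self, n, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        base = demean(rng.standard_normal(16))
        maps = base + 0.5 * rng.standard_normal((n, 16))
        return demean(maps) + shift

    def test_identical_groups_give_effect_zero_p_one(self):
        maps = self._maps(10, 0)
        res = md.tanova_topography(maps, maps.copy(), n_perm=500, seed=1)
        assert res.observed_effect == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_invariant_to_group_order(self):
        a, b = self._maps(12, 2), self._maps(12, 3)
        p1 = md.tanova_topography(a, b, n_perm=400, seed=7).p_value
        p2 = md.tanova_topography(b, a, n_perm=400, seed=7).p_value
        assert p1 == pytest.approx(p2, abs=0.02)  # same statistic, resampled null

    def test_p_bounded_below_by_permutation_count(self):
        rng = np.random.default_rng(4)
        a = demean(rng.standard_normal((8, 16)))
        b = demean(rng.standard_normal((8, 16))) + demean(np.arange(16.0)) * 3
        res = md.tanova_topography(a, b, n_perm=200, seed=5)
        assert res.p_value >= 1.0 / 201.0

    def test_planted_difference_detected(self):
        # planted topographic shift of one noise SD, n = 43 + 43
        rng = np.random.default_rng(6)
        t1 = demean(rng.standard_normal(16))
        shift = demean(rng.standard_normal(16))
        shift /= shift.std()
        a = demean(t1 + rng.standard_normal((43, 16)))
        b = demean(t1 + shift + rng.standard_normal((43, 16)))
        res = md.tanova_topography(a, b, n_perm=5000, seed=8)
        assert res.p_value <= 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            md.tanova_topography(self._maps(1, 0), self._maps(5, 1), n_perm=100)


class TestMixedAnova:
    def test_identical_groups_give_zero_treatment_f(self):
        df = anova_long(effect=0.0, sd=0.0)
        res = mixed_anova(df)
        assert res["treatment"].F == pytest.approx(0.0, abs=1e-12)
        assert res["treatment"].p == 1.0

    def test_matches_pingouin_cross_check(self):
        df = anova_long(n_per=8, effect=4.0, seed=3)
        res = mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="level",
                             subject="subject_id", between="group", correction=True)
        ref = ref.set_index("Source")
        assert res["treatment"].F == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert res["class"].F == pytest.approx(ref.loc["level", "F"], abs=1e-8)
        assert res["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)
        assert res["class"].epsilon == pytest.approx(ref.loc["level", "eps"], abs=1e-8)
        assert res["class"].eta_sq_partial == pytest.approx(
            ref.loc["level", "np2"], abs=1e-8)

    def test_sums_of_squares_add_to_total(self):
        df = anova_long(n_per=7, effect=3.0, seed=4)
        res = mixed_anova(df)
        wide = df.pivot_table(index="subject_id", columns="level", values="value")
        total = float(((wide.to_numpy() - wide.to_numpy().mean()) ** 2).sum())
        parts = (res["treatment"].ss + res["treatment"].ss_error
                 + res["class"].ss + res["interaction"].ss + res["class"].ss_error)
        assert parts == pytest.approx(total, abs=1e-8)

    def test_gg_epsilon_one_under_compound_symmetry(self):
        # spherical-by-construction within covariance at large n; the sample
        # GG estimator is biased downward at moderate n, so n is large here
        rng = np.random.default_rng(5)
        n = 1000
        subj = rng.normal(0, 3.0, size=n)[:, None]
        y = 75 + subj + rng.normal(0, 2.0, size=(n, 4))
        rows = []
        for i in range(n):
            for j, c in enumerate("ABCD"):
                rows.append(dict(subject_id=f"S{i:03d}",
                                 group="treatment" if i < n // 2 else "placebo",
                                 level=c, value=y[i, j]))
        res = mixed_anova(pd.DataFrame(rows))
        assert res["class"].epsilon == pytest.approx(1.0, abs=0.02)

    def test_gg_correction_only_when_mauchly_rejects(self):
        df = anova_long(n_per=8, seed=6)
        res = mixed_anova(df)
        for term in ("class", "interaction"):
            r = res[term]
            expected = r.p_gg if r.mauchly_p < 0.05 else r.p_uncorrected
            assert r.p == expected


class TestFollowup:
    def test_equal_groups_give_zero_f(self):
        v = np.r_[np.ones(5) * 3, np.ones(5) * 3]
        g = np.r_[["a"] * 5, ["b"] * 5]
        res = followup_oneway(v, g)
        assert res.F == 0.0 and res.p == 1.0

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(7)
        v = np.r_[rng.normal(0, 1, 20), rng.normal(0.8, 1.3, 25)]
        g = np.r_[["a"] * 20, ["b"] * 25]
        from scipy import stats as sps

        t, _ = sps.ttest_ind(v[:20], v[20:], equal_var=True)
        res = followup_oneway(v, g)
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(8)
        v = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10)]
        g = np.r_[["a"] * 10, ["b"] * 10]
        res = followup_oneway(v, g, bonferroni_m=12)
        assert res.p_adjusted == min(1.0, 12 * res.p)
        assert res.p_adjusted >= res.p


class TestModeration:
    def test_exact_interaction_matches_lstsq_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        g = np.r_[["treatment"] * 20, ["placebo"] * 20]
        z = rng.standard_normal(n)
        code = (g == "treatment").astype(float)
        y = 3.0 * code * (z - z.mean())  # outcome = group × centred moderator
        res = moderation_analysis(y, g, z, group_order=("placebo", "treatment"))
        # independent least-squares oracle
        zc = z - z.mean()
        X1 = np.column_stack([np.ones(n), code, zc])
        X2 = np.column_stack([X1, code * zc])
        def r2(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        expected = 100 * (r2(X2) - r2(X1))
        assert res.delta_r_sq == pytest.approx(expected, abs=1e-8)
        assert res.p_interaction < 1e-12

    def test_within_group_correlations_reported(self):
        rng = np.random.default_rng(10)
        n = 60
        g = np.r_[["treatment"] * 30, ["placebo"] * 30]
        z = rng.standard_normal(n)
        y = np.where(g == "treatment", 2.0 * z, 0.0) + rng.standard_normal(n) * 0.5
        res = moderation_analysis(y, g, z)
        r_t, p_t, df_t = res.within_group["treatment"]
        r_p, _, _ = res.within_group["placebo"]
        assert df_t == 28
        assert r_t > 0.8 and abs(r_p) < 0.5

    def test_constant_moderator_rejected(self):
        g = np.r_[["a"] * 5, ["b"] * 5]
        with pytest.raises(ValueError, match="constant"):
            moderation_analysis(np.arange(10.0), g, np.ones(10))


class TestNullCalibration:
    """Type-I error of the permutation and interaction tests (reduced reps;
    the full 1000-replicate calibration lives in the acceptance suite)."""

    def test_tanova_null_rejection_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            maps = demean(rng.standard_normal((20, 12)))
            res = md.tanova_topography(maps[:10], maps[10:], n_perm=199, seed=rng)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_moderation_null_rejection_rate(self):
        rng = np.random.default_rng(12)
        g = np.r_[["treatment"] * 43, ["placebo"] * 43]
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            y = rng.standard_normal(86)
            z = rng.standard_normal(86)
            res = moderation_analysis(y, g, z)
            rejections += res.p_interaction < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09
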