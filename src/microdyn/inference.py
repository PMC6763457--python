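"""Group-level statistics for microstate analyses.

Four procedures:

* :func:`tanova_topography` — nonparametric randomization test (TANOVA)
  comparing the mean scalp topography of two groups, per microstate class.
  Effect measure: GFP of the difference between group-mean maps after each
  subject map is normalised to unit GFP; the null is built by permuting group
  labels, and the observed partition is counted into the null so that
  p ≥ 1/(n_perm+1).

* :func:`mixed_anova` — split-plot (one between-subject factor × one
  within-subject factor) ANOVA with Mauchly's sphericity test and
  Greenhouse–Geisser correction of the within-stratum degrees of freedom.
  The decomposition is computed here (between stratum on subject means;
  within stratum on subject-centred data via Type-III effect coding) because
  the GG correction must be applied to the interaction term as well as the
  within main effect. Effect sizes are partial η².

* :func:`followup_oneway` — two-group one-way ANOVA per cell with optional
  Bonferroni correction (m = 12 for the transition cells).

* :func:`moderation_analysis` — simple-moderation (interaction) regression:
  outcome on group code (0/1) and the grand-mean-centred moderator, then
  adding their product; ΔR² with its F(1, n−4) test, plus within-group
  Pearson correlations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from .containers import CohortTable
from .topoclust import compute_gfp


# --------------------------------------------------------------------------- #
# TANOVA
# --------------------------------------------------------------------------- #

@dataclass
class TanovaResult:
    observed_effect: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int


def tanova_topography(
    maps_g1: np.ndarray,
    maps_g2: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> TanovaResult:
    """Randomization test for a topographic difference between two groups.

    ``maps_g1`` / ``maps_g2`` hold one topography per subject (n_subj, C).
    Subject maps are normalised to unit GFP so the test is amplitude-blind.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = np.asarray(maps_g1, dtype=float)
    g2 = np.asarray(maps_g2, dtype=float)
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subject maps")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a very coarse p-value")
    M = np.concatenate([g1, g2], axis=0)
    M = M - M.mean(axis=1, keepdims=True)
    gfp = M.std(axis=1, ddof=0)
    if (gfp == 0).any():
        raise ValueError("zero-variance subject map in TANOVA input")
    M = M / gfp[:, None]
    n = n1 + n2

    def effect(ind: np.ndarray) -> np.ndarray:
        # ind: (P, n) boolean, True → group 1
        s1 = ind @ M
        diff = s1 / n1 - (M.sum(axis=0) - s1) / n2
        return diff.std(axis=1, ddof=0)

    obs = float(effect(np.r_[np.ones(n1), np.zeros(n2)][None, :])[0])
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    ind = np.zeros((n_perm, n))
    np.put_along_axis(ind, order[:, :n1], 1.0, axis=1)
    null = effect(ind)
    # tolerance keeps exactly-tied permutations (e.g. identical groups) counted
    thr = obs - max(1e-12, 1e-9 * obs)
    p = (np.count_nonzero(null >= thr) + 1) / (n_perm + 1)
    return TanovaResult(observed_effect=obs, null_distribution=null,
                        p_value=float(p), n_perm=n_perm)


# --------------------------------------------------------------------------- #
# Split-plot ANOVA
# --------------------------------------------------------------------------- #

@dataclass
class AnovaResult:
    term: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    epsilon: float | None = None
    p_gg: float | None = None
    p: float = float("nan")  # the p-value to report (GG-corrected if warranted)
    eta_sq_partial: float = float("nan")
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    ss: float = float("nan")
    ss_error: float = float("nan")


def _effect_codes(levels: pd.Index, values: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding: (n, L-1)."""
    L = len(levels)
    out = np.zeros((len(values), L - 1))
    codes = pd.Categorical(values, categories=levels).codes
    for j in range(L - 1):
        out[codes == j, j] = 1.0
    out[codes == L - 1, :] = -1.0
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mixed_anova(
    ct: CohortTable | pd.DataFrame,
    dv: str = "duration",
    alpha_sphericity: float = 0.05,
) -> dict[str, AnovaResult]:
    """Split-plot ANOVA: between factor = treatment group, within factor =
    microstate class (or the 12 class transitions for ``dv="transitions"``).

    Accepts a :class:`CohortTable` plus a characteristic name, or directly a
    tidy frame with columns ``subject_id, group, level, value``. Subjects with
    any missing cell are dropped listwise with a warning. The reported ``p``
    of the within-stratum terms is Greenhouse–Geisser corrected when Mauchly's
    test rejects sphericity at ``alpha_sphericity``.
    """
    long = ct.long(dv) if isinstance(ct, CohortTable) else ct.copy()
    wide = long.pivot_table(index="subject_id", columns="level", values="value")
    groups = long.drop_duplicates("subject_id").set_index("subject_id")["group"]
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"dropped {len(wide) - len(complete)} subject(s) with missing cells"
        )
    wide = complete
    g = groups.loc[wide.index]
    levels = wide.columns
    k = len(levels)
    group_levels = pd.Index(sorted(g.unique()))
    n = len(wide)
    n_g = len(group_levels)
    if n_g < 2:
        raise ValueError("need at least two groups")

    Y = wide.to_numpy(dtype=float)
    subj_means = Y.mean(axis=1)

    # ---- between stratum: one-way ANOVA on subject means (scaled by k) ----
    grand = subj_means.mean()
    ss_between_total = k * float(((subj_means - grand) ** 2).sum())
    means_g = np.array([subj_means[(g == gl).to_numpy()].mean() for gl in group_levels])
    counts = np.array([(g == gl).sum() for gl in group_levels])
    ss_group = k * float((counts * (means_g - grand) ** 2).sum())
    ss_subj = ss_between_total - ss_group
    df_group, df_subj = n_g - 1, n - n_g
    ms_group, ms_subj = ss_group / df_group, ss_subj / df_subj
    F_group = ms_group / ms_subj if ms_subj > 0 else (0.0 if ss_group == 0 else np.inf)
    p_group = float(stats.f.sf(F_group, df_group, df_subj)) if np.isfinite(F_group) else 0.0
    if ss_group == 0 and ms_subj == 0:
        F_group, p_group = 0.0, 1.0

    # ---- within stratum on subject-centred data, Type-III effect coding ----
    E = (Y - subj_means[:, None]).ravel()  # subject i varies slowest
    cls_long = pd.Series(np.tile(np.arange(k), n))
    grp_long = pd.Series(np.repeat(pd.Categorical(g, categories=group_levels).codes, k))
    C = _effect_codes(pd.Index(range(k)), cls_long)
    G = _effect_codes(pd.Index(range(n_g)), grp_long)
    GC = np.einsum("ij,il->ijl", G, C).reshape(len(E), -1)
    X_full = np.hstack([C, GC])
    rss_full = _rss(E, X_full)
    ss_class = _rss(E, GC) - rss_full
    ss_int = _rss(E, C) - rss_full
    df_class, df_int = k - 1, (n_g - 1) * (k - 1)
    df_err = (n - n_g) * (k - 1)
    ms_err = rss_full / df_err

    # sphericity diagnostics on the within-factor covariance
    long_pg = pd.DataFrame({
        "subject_id": np.repeat(wide.index.to_numpy(), k),
        "level": np.tile(np.asarray(levels), n),
        "value": Y.ravel(),
    })
    if k > 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spher = pg.sphericity(long_pg, dv="value", within="level",
                                  subject="subject_id")
            eps = float(pg.epsilon(long_pg, dv="value", within="level",
                                   subject="subject_id", correction="gg"))
        mauchly_w, mauchly_p = float(spher.W), float(spher.pval)
        if not np.isfinite(eps):  # degenerate (e.g. zero-variance) input
            eps = 1.0
        if not np.isfinite(mauchly_p):
            mauchly_p = 1.0
    else:
        eps, mauchly_w, mauchly_p = 1.0, 1.0, 1.0
    use_gg = mauchly_p < alpha_sphericity

    def within_term(name: str, ss: float, df1: int) -> AnovaResult:
        F = (ss / df1) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        if ss == 0 and ms_err == 0:
            Fv, p_unc = 0.0, 1.0
        else:
            Fv = float(F)
            p_unc = float(stats.f.sf(Fv, df1, df_err)) if np.isfinite(Fv) else 0.0
        p_gg = float(stats.f.sf(Fv, df1 * eps, df_err * eps)) if np.isfinite(Fv) else 0.0
        return AnovaResult(
            term=name, F=Fv, df_num=df1, df_den=df_err,
            p_uncorrected=p_unc, epsilon=eps, p_gg=p_gg,
            p=p_gg if use_gg else p_unc,
            eta_sq_partial=ss / (ss + rss_full) if (ss + rss_full) > 0 else 0.0,
            mauchly_w=mauchly_w, mauchly_p=mauchly_p,
            ss=ss, ss_error=rss_full,
        )

    res_group = AnovaResult(
        term="treatment", F=float(F_group), df_num=df_group, df_den=df_subj,
        p_uncorrected=p_group, p=p_group,
        eta_sq_partial=ss_group / (ss_group + ss_subj) if (ss_group + ss_subj) > 0 else 0.0,
        ss=ss_group, ss_error=ss_subj,
    )
    return {
        "treatment": res_group,
        "class": within_term("class", ss_class, df_class),
        "interaction": within_term("treatment × class", ss_int, df_int),
    }


def anova_table(results: dict[str, AnovaResult]) -> pd.DataFrame:
    rows = []
    for r in results.values():
        rows.append({
            "term": r.term, "F": r.F, "df_num": r.df_num, "df_den": r.df_den,
            "epsilon": r.epsilon, "p_unc": r.p_uncorrected, "p_gg": r.p_gg,
            "p": r.p, "eta_sq_partial": r.eta_sq_partial,
            "mauchly_W": r.mauchly_w, "mauchly_p": r.mauchly_p,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Follow-up one-way ANOVAs
# --------------------------------------------------------------------------- #

@dataclass
class OnewayResult:
    F: float
    df_num: int
    df_den: int
    p: float
    p_adjusted: float
    eta_sq: float
    group_means: dict[str, float] = field(default_factory=dict)


def followup_oneway(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    bonferroni_m: int | None = None,
) -> OnewayResult:
    """Two-group one-way ANOVA on a single microstate characteristic cell.

    ``bonferroni_m`` multiplies the p-value by m (capped at 1), as applied to
    the 12 transition cells for which no a-priori hypothesis exists.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("followup_oneway expects exactly two groups")
    a, b = (values[groups == gl] for gl in levels)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(a, b)
        F, p = float(F), float(p)
    n = len(values)
    grand = values.mean()
    ss_b = sum(len(x) * (x.mean() - grand) ** 2 for x in (a, b))
    ss_t = float(((values - grand) ** 2).sum())
    p_adj = min(1.0, bonferroni_m * p) if bonferroni_m else p
    return OnewayResult(
        F=F, df_num=1, df_den=n - 2, p=p, p_adjusted=float(p_adj),
        eta_sq=ss_b / ss_t if ss_t > 0 else 0.0,
        group_means={str(gl): float(values[groups == gl].mean()) for gl in levels},
    )


# --------------------------------------------------------------------------- #
# Moderation
# --------------------------------------------------------------------------- #

@dataclass
class ModerationResult:
    delta_r_sq: float  # in % of variance
    F_interaction: float
    df_num: int
    df_den: int
    p_interaction: float
    within_group: dict[str, tuple[float, float, int]]  # group -> (r, p, df)
    coef_interaction: float


def moderation_analysis(
    outcome: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
    moderator: pd.Series | np.ndarray,
    group_order: tuple[str, str] | None = None,
) -> ModerationResult:
    """Simple-moderation regression (hierarchical interaction test).

    Model 1: outcome ~ group(0/1) + moderator (grand-mean centred).
    Model 2: adds group × moderator. ΔR² = R²₂ − R²₁ with F(1, n−4).
    Also reports the Pearson correlation between moderator and outcome within
    each group (df = n_group − 2).
    """
    y = np.asarray(outcome, dtype=float)
    grp = np.asarray(group)
    m = np.asarray(moderator, dtype=float)
    if np.std(m) == 0:
        raise ValueError("moderator is constant")
    levels = list(group_order) if group_order else sorted(np.unique(grp).tolist())
    if len(levels) != 2:
        raise ValueError("moderation analysis expects exactly two groups")
    code = (grp == levels[1]).astype(float)  # second level coded 1
    mc = m - m.mean()
    n = len(y)
    X1 = sm.add_constant(np.column_stack([code, mc]))
    X2 = sm.add_constant(np.column_stack([code, mc, code * mc]))
    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit()
    r2_1, r2_2 = fit1.rsquared, fit2.rsquared
    df_den = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (1.0 - r2_2) / df_den
        F = float((r2_2 - r2_1) / denom) if denom > 0 else np.inf
    p = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
    within = {}
    for gl in levels:
        sel = grp == gl
        ng = int(sel.sum())
        if ng >= 3 and np.std(m[sel]) > 0 and np.std(y[sel]) > 0:
            r, pr = stats.pearsonr(m[sel], y[sel])
            within[str(gl)] = (float(r), float(pr), ng - 2)
        else:
            within[str(gl)] = (float("nan"), float("nan"), max(ng - 2, 0))
    return ModerationResult(
        delta_r_sq=100.0 * float(r2_2 - r2_1),
        F_interaction=F,
        df_num=1,
        df_den=df_den,
        p_interaction=p,
        within_group=within,
        coef_interaction=float(fit2.params[3]),
    )
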