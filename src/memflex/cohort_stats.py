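"""Cohort-level statistics for white-matter and cognitive data.

Covers the human/animal quantitative pipeline around fractional
anisotropy (FA): the relative FA change (dFA) and its cross-ROI effect
contrasts, ROI-wise two-sample tests with Benjamini-Hochberg FDR
control, pooled t-tests from printed summary statistics, corrected
total fluorescence (CTF) for immunostain quantification, a PCA-derived
cognitive composite (PC1), and the age-partialled Kendall correlation
between FA and cognition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RoiEffect",
    "EffectContrast",
    "CognitivePC1",
    "delta_fa",
    "effect_contrast",
    "roi_group_tests",
    "summary_t_test",
    "ctf",
    "cognitive_pc1",
    "partial_kendall",
    "partial_tau_from_taus",
    "screen_cognitive_variables",
    "fa_cognition_association",
]


def delta_fa(fa_ref_mean: float, fa_case_mean: float) -> float:
    """Relative FA change (case - reference) / reference."""
    if fa_ref_mean <= 0:
        raise ValueError("reference FA mean must be positive")
    return (fa_case_mean - fa_ref_mean) / fa_ref_mean


@dataclass(frozen=True)
class EffectContrast:
    """How much larger the target ROI's |dFA| is than its competitors."""

    target_roi: str
    pct_vs_runner_up: float
    pct_vs_mean: float
    runner_up_roi: str
    averaging_rois: tuple[str, ...]
    target_is_max: bool


def effect_contrast(effects: dict[str, float], target_roi: str
                    ) -> EffectContrast:
    """Percent excess of |dFA| in the target ROI vs runner-up and mean.

    ``effects`` maps ROI name to its (signed) dFA among the affected
    ROIs; contrasts are on magnitudes.  The averaging set is the other
    affected ROIs (target excluded).  If the target is not the largest
    effect this is reported via ``target_is_max``, not raised.
    """
    if target_roi not in effects:
        raise KeyError(f"target ROI {target_roi!r} not in effects")
    if len(effects) < 2:
        raise ValueError("need at least two ROIs to contrast")
    mags = {roi: abs(e) for roi, e in effects.items()}
    target = mags.pop(target_roi)
    runner_roi = max(mags, key=mags.get)  # type: ignore[arg-type]
    runner = mags[runner_roi]
    mean_others = float(np.mean(list(mags.values())))
    if runner == 0 or mean_others == 0:
        raise ValueError("competitor effects are all zero")
    return EffectContrast(
        target_roi=target_roi,
        pct_vs_runner_up=100.0 * (target - runner) / runner,
        pct_vs_mean=100.0 * (target - mean_others) / mean_others,
        runner_up_roi=runner_roi,
        averaging_rois=tuple(sorted(mags)),
        target_is_max=target >= runner)


@dataclass(frozen=True)
class RoiEffect:
    """Group comparison in one ROI."""

    roi: str
    delta_fa: float
    t: float
    df: float
    p_raw: float
    p_fdr: float
    significant: bool
    sidedness: str
    zero_variance: bool


def roi_group_tests(table: pd.DataFrame, roi_columns: list[str] | None = None,
                    group_col: str = "group", case_label: str = "case",
                    alpha: float = 0.05, sidedness: str = "two-sided"
                    ) -> pd.DataFrame:
    """Per-ROI pooled two-sample t-tests with Benjamini-Hochberg FDR.

    ``sidedness`` is ``"two-sided"`` (human ROI analyses) or ``"less"``
    / ``"greater"`` for directed one-tailed tests on the case-minus-
    reference difference (the animal analyses used one-tailed tests).
    Rows with missing values in an ROI are dropped for that ROI only;
    zero-variance ROIs are flagged.  Returns a tidy frame with one
    :class:`RoiEffect` row per ROI.
    """
    if sidedness not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    groups = table[group_col].unique()
    if len(groups) != 2 or case_label not in groups:
        raise ValueError("exactly two group labels required, one being "
                         f"{case_label!r}")
    ref_label = next(g for g in groups if g != case_label)
    if roi_columns is None:
        roi_columns = [c for c in table.columns
                       if c not in (group_col, "subject", "age")]
    rows = []
    for roi in roi_columns:
        case = table.loc[table[group_col] == case_label, roi].dropna()
        ref = table.loc[table[group_col] == ref_label, roi].dropna()
        if len(case) < 2 or len(ref) < 2:
            raise ValueError(f"ROI {roi!r}: need >= 2 subjects per group")
        zero_var = case.var(ddof=1) == 0 and ref.var(ddof=1) == 0
        if zero_var:
            t_val, p_val = float("nan"), 1.0
        else:
            t_val, p_val = stats.ttest_ind(case, ref, equal_var=True,
                                           alternative=sidedness)
        rows.append({
            "roi": roi,
            "delta_fa": delta_fa(ref.mean(), case.mean()),
            "t": float(t_val),
            "df": float(len(case) + len(ref) - 2),
            "p_raw": float(p_val),
            "sidedness": sidedness,
            "zero_variance": bool(zero_var),
        })
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha,
                                        method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out[["roi", "delta_fa", "t", "df", "p_raw", "p_fdr",
                "significant", "sidedness", "zero_variance"]]


def summary_t_test(m1: float, sd1: float, n1: int,
                   m2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled two-sample t from summary statistics; returns (t, df).

    t is for the difference m2 - m1; df = n1 + n2 - 2.  Lets printed
    group summaries (mean, SD, n) be checked without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            raise ValueError("t undefined: zero variance and equal means")
    res = stats.ttest_ind_from_stats(m2, sd2, n2, m1, sd1, n1,
                                     equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2)


def ctf(integrated_density: float, area: float,
        mean_background: float) -> float:
    """Corrected total fluorescence: IntDen - area * mean background.

    Integrated density is mean fluorescence times area; a negative CTF
    (background brighter than the ROI) is permitted and logged by the
    caller, not an error.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return integrated_density - area * mean_background


@dataclass
class CognitivePC1:
    """First principal component of standardized cognitive scores."""

    scores: np.ndarray
    loadings: pd.Series
    variance_explained: float  # fraction of total variance in PC1
    variance_fractions: np.ndarray
    oriented_worse_high: bool


def cognitive_pc1(table: pd.DataFrame, variables: list[str],
                  worse_when_higher: dict[str, bool] | None = None
                  ) -> CognitivePC1:
    """PCA composite of cognitive tests on the correlation structure.

    Variables are z-scored, so the PCA acts on the correlation matrix.
    The PC1 sign is oriented so that larger PC1 means worse performance:
    by default a higher raw score is taken as worse (completion times,
    error counts); set ``worse_when_higher[var] = False`` for scores
    where higher is better (e.g. items completed).
    """
    if len(variables) < 2:
        raise ValueError("PCA composite needs at least 2 variables")
    data = table[variables].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete subjects")
    sds = data.std(ddof=1)
    for var in variables:
        if sds[var] == 0:
            raise ValueError(f"constant variable {var!r} cannot be "
                             "standardized")
    z = (data - data.mean()) / sds
    pca = PCA(n_components=len(variables))
    scores = pca.fit_transform(z.to_numpy())
    loadings = pd.Series(pca.components_[0], index=variables)
    direction = np.array([
        1.0 if (worse_when_higher or {}).get(v, True) else -1.0
        for v in variables])
    # flip so the badness-aligned loading sum is positive
    if float(loadings.to_numpy() @ direction) < 0:
        loadings = -loadings
        scores = -scores
    fractions = pca.explained_variance_ratio_
    return CognitivePC1(scores=scores[:, 0], loadings=loadings,
                        variance_explained=float(fractions[0]),
                        variance_fractions=fractions,
                        oriented_worse_high=True)


def partial_tau_from_taus(t_xy: float, t_xz: float, t_yz: float) -> float:
    """Partial Kendall tau from the three pairwise taus.

    tau_xy.z = (tau_xy - tau_xz * tau_yz)
               / sqrt((1 - tau_xz^2) (1 - tau_yz^2)).
    """
    denom_sq = (1 - t_xz ** 2) * (1 - t_yz ** 2)
    # tolerance absorbs floating-point tau values a hair below 1
    if denom_sq <= 1e-12:
        raise ValueError("partial tau undefined: a control correlation "
                         "has |tau| = 1")
    return float((t_xy - t_xz * t_yz) / math.sqrt(denom_sq))


def partial_kendall(x, y, z) -> float:
    """Kendall tau-b of x and y with z partialled out.

    Composes :func:`partial_tau_from_taus` over the three pairwise
    tau-b (tie-corrected) correlations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal lengths")
    if x.size < 4:
        raise ValueError("partial Kendall tau needs n >= 4")
    t_xy = stats.kendalltau(x, y).statistic
    t_xz = stats.kendalltau(x, z).statistic
    t_yz = stats.kendalltau(y, z).statistic
    return partial_tau_from_taus(t_xy, t_xz, t_yz)


def screen_cognitive_variables(table: pd.DataFrame, fa_col: str,
                               candidates: list[str],
                               alpha: float = 0.05) -> list[str]:
    """Variables whose Pearson correlation with FA is significant.

    The screening step before building the PCA composite: only tests
    that track the microstructural measure enter the composite.
    """
    kept = []
    for var in candidates:
        sub = table[[fa_col, var]].dropna()
        if len(sub) < 3:
            continue
        r = stats.pearsonr(sub[fa_col], sub[var])
        if r.pvalue < alpha:
            kept.append(var)
    return kept


def fa_cognition_association(table: pd.DataFrame, fa_col: str,
                             cognitive_vars: list[str], age_col: str = "age",
                             worse_when_higher: dict[str, bool] | None = None,
                             screen_alpha: float = 0.05,
                             screen: bool = True) -> dict:
    """FA-cognition association controlling for age, end to end.

    Screens the cognitive variables against FA (optional), builds the
    PC1 composite, and returns the raw and age-partialled Kendall tau
    between FA and PC1, under both sign orientations of PC1.
    """
    variables = cognitive_vars
    if screen:
        variables = screen_cognitive_variables(table, fa_col,
                                               cognitive_vars, screen_alpha)
        if len(variables) < 2:
            variables = cognitive_vars  # screening too strict; use all
    data = table[[fa_col, age_col] + variables].dropna()
    pc1 = cognitive_pc1(data, variables, worse_when_higher)
    fa = data[fa_col].to_numpy()
    age = data[age_col].to_numpy()
    raw_tau = stats.kendalltau(fa, pc1.scores).statistic
    p_tau = partial_kendall(fa, pc1.scores, age)
    return {
        "variables": variables,
        "pc1_variance_explained": pc1.variance_explained,
        "tau_raw": float(raw_tau),
        "tau_partial": float(p_tau),
        "tau_raw_flipped": float(-raw_tau),
        "tau_partial_flipped": float(-p_tau),
        "n": int(len(data)),
    }
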