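"""Group-comparison statistics, FDR correction, and correlation analysis.

Two-group comparisons pick their test from the data: Shapiro-Wilk normality
on each group at alpha = 0.05 routes to a two-sample t-test when both groups
look normal, otherwise to the Mann-Whitney U test (normal approximation with
tie correction). Welch's unequal-variance t-test is available as a forced
mode for the genus-abundance contrasts. P-values are corrected with the
Benjamini-Hochberg step-up procedure. Biomarker analysis correlates genus
relative abundances with total-protein-normalized biomarker levels (Pearson),
and qPCR concordance is Pearson on inverse-hyperbolic-sine-transformed pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(slots=True)
class StatResult:
    feature: str
    group_a: str
    group_b: str
    test: str  # student_t | welch_t | mann_whitney | degenerate
    statistic: float
    p: float
    q: float | None = None
    n_a: int = 0
    n_b: int = 0


def compare_groups(a, b, mode: str = "auto", feature: str = "",
                   group_a: str = "A", group_b: str = "B",
                   normality_alpha: float = 0.05) -> StatResult:
    """Two-group comparison with normality-dependent test selection.

    ``mode``: ``auto`` (Shapiro-Wilk routing), ``student`` / ``welch``
    (t-tests), or ``mwu``. Groups that are both constant are handled
    explicitly: p = 1 when they are identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        return StatResult(feature, group_a, group_b, "degenerate", 0.0,
                          1.0 if same else 0.0, n_a=len(a), n_b=len(b))
    if mode == "auto":
        if len(a) >= 3 and len(b) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
            normal = (sps.shapiro(a).pvalue > normality_alpha
                      and sps.shapiro(b).pvalue > normality_alpha)
        else:
            normal = False
        mode = "student" if normal else "mwu"
    if mode in ("student", "welch"):
        res = sps.ttest_ind(a, b, equal_var=(mode == "student"))
        test = "student_t" if mode == "student" else "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # zero variance in both with equal means already
            stat, p = 0.0, 1.0  # handled above; residual degenerate case
    elif mode == "mwu":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult(feature, group_a, group_b, test, stat, min(p, 1.0),
                      n_a=len(a), n_b=len(b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_feature_table(values: pd.DataFrame, groups: pd.Series,
                          contrasts: list[tuple[str, str]],
                          mode: str = "auto") -> pd.DataFrame:
    """Per-feature group comparisons with BH adjustment within each contrast.

    ``values``: samples x features. Returns a tidy table of StatResults.
    """
    groups = groups.reindex(values.index)
    rows: list[StatResult] = []
    for ga, gb in contrasts:
        results = []
        for feature in values.columns:
            a = values.loc[groups == ga, feature].to_numpy()
            b = values.loc[groups == gb, feature].to_numpy()
            results.append(compare_groups(a, b, mode=mode, feature=feature,
                                          group_a=ga, group_b=gb))
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
        rows.extend(results)
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def pearson_with_p(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # genus x biomarker
    p: pd.DataFrame
    q: pd.DataFrame
    stars: pd.DataFrame


def pearson_matrix(genus_abundance: pd.DataFrame, biomarkers: pd.DataFrame,
                   total_protein_col: str = "total_protein",
                   ) -> CorrelationMatrix:
    """Genus x biomarker Pearson correlations on paired subjects.

    Biomarker levels are divided by each subject's total protein before
    correlating; BH adjustment runs across the whole matrix. Zero-variance
    vectors yield NaN entries flagged by an empty star string.
    """
    if total_protein_col not in biomarkers.columns:
        raise ValueError(f"biomarkers table lacks {total_protein_col!r}")
    shared = genus_abundance.index.intersection(biomarkers.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired subjects")
    ga = genus_abundance.loc[shared]
    marker_cols = [c for c in biomarkers.columns
                   if c not in (total_protein_col, "group")]
    normalized = biomarkers.loc[shared, marker_cols].div(
        biomarkers.loc[shared, total_protein_col], axis=0)
    r = pd.DataFrame(index=ga.columns, columns=marker_cols, dtype=float)
    p = r.copy()
    for genus in ga.columns:
        for marker in marker_cols:
            r.loc[genus, marker], p.loc[genus, marker] = pearson_with_p(
                ga[genus], normalized[marker])
    flat_p = p.to_numpy().ravel()
    valid = ~np.isnan(flat_p)
    flat_q = np.full_like(flat_p, np.nan)
    if valid.any():
        flat_q[valid] = bh_adjust(flat_p[valid])
    q = pd.DataFrame(flat_q.reshape(p.shape), index=p.index, columns=p.columns)
    stars = q.map(lambda v: "" if np.isnan(v) else _stars(v))
    return CorrelationMatrix(r, p, q, stars)


def linear_fit(x, y) -> tuple[float, float, float]:
    """OLS fit y = slope*x + intercept; returns (slope, intercept, p).

    The slope p-value is identical to the Pearson correlation p-value for
    the same pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def asinh_transform(x) -> np.ndarray:
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)): log-like but defined
    at zero, which read counts and copy numbers frequently are."""
    return np.arcsinh(np.asarray(x, dtype=float))


def fisher_z_interval(r: float, n: int, conf: float = 0.95,
                      ) -> tuple[float, float]:
    """Confidence interval for a Pearson correlation via the Fisher
    z-transform (atanh(r) +- z* / sqrt(n - 3))."""
    if n <= 3:
        raise ValueError("need n > 3")
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def qpcr_concordance(read_counts, copy_numbers) -> tuple[float, float]:
    """Pearson r (and p) between asinh-transformed 16S read counts and
    asinh-transformed qPCR copy numbers over paired samples."""
    x = asinh_transform(read_counts)
    y = asinh_transform(copy_numbers)
    if len(x) != len(y):
        raise ValueError("read counts and copy numbers must be paired")
    return pearson_with_p(x, y)
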