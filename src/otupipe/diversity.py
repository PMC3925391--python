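"""Alpha-diversity estimators over per-sample OTU abundance vectors.

All diversity indices use the natural logarithm. Richness estimators follow
the standard nonparametric forms: bias-corrected Chao1
``S_obs + F1(F1-1)/(2(F2+1))`` (the classic ``S_obs + F1^2/(2 F2)`` is
available behind a switch) and ACE with the conventional rare-species cutoff
of 10. Fisher's alpha solves ``S = alpha * ln(1 + N/alpha)`` by bisection.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def _clean(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("abundance vector has no positive counts")
    return v


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural log)."""
    v = _clean(counts)
    p = v / v.sum()
    return float(-(p * np.log(p)).sum())


def simpson_family(counts) -> tuple[float, float]:
    """(Simpson index 1 - lambda, inverse Simpson 1/lambda)."""
    v = _clean(counts)
    p = v / v.sum()
    lam = float((p * p).sum())
    return 1.0 - lam, 1.0 / lam


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton frequencies."""
    v = _clean(counts)
    s_obs = v.size
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # standard f2=0 fallback
    return s_obs + f1 * f1 / (2.0 * f2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness."""
    v = _clean(counts)
    rare = v[v <= rare_cutoff]
    s_abund = int((v > rare_cutoff).sum())
    s_rare = rare.size
    n_rare = int(rare.sum())
    f1 = int((v == 1).sum())
    if n_rare == 0:
        return chao1(v)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(v)
    ssq = sum(k * (k - 1) * int((rare == k).sum())
              for k in range(1, rare_cutoff + 1))
    if n_rare > 1:
        gamma2 = max((s_rare / c_ace) * ssq / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def fisher_alpha(counts, tol: float = 1e-10) -> float:
    """Fisher's log-series alpha: solves S = alpha ln(1 + N/alpha)."""
    v = _clean(counts)
    s, n = float(v.size), float(v.sum())
    if s >= n:
        raise ValueError("Fisher's alpha undefined when all counts are 1")

    def f(alpha: float) -> float:
        return alpha * math.log1p(n / alpha) - s

    lo, hi = 1e-8, 1e8
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - guarded by s < n
        raise ValueError("Fisher's alpha bracket failed")
    while True:
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) < tol or (hi - lo) < 1e-14 * max(1.0, mid):
            return mid
        if val > 0:
            hi = mid
        else:
            lo = mid


def pielou(counts) -> float:
    """Pielou's evenness J = H / ln S_obs; undefined for a single species."""
    v = _clean(counts)
    if v.size < 2:
        raise ValueError("Pielou's evenness needs at least 2 species")
    return shannon(v) / math.log(v.size)


def diversity_profile(counts) -> dict[str, float]:
    """The full per-sample panel of richness/evenness/diversity estimates."""
    v = _clean(counts)
    d_simpson, d_inv = simpson_family(v)
    s_obs = int(v.size)
    n = float(v.sum())
    return {
        "n_reads": n,
        "observed_otus": s_obs,
        "shannon": shannon(v),
        "simpson": d_simpson,
        "invsimpson": d_inv,
        "fisher_alpha": fisher_alpha(v) if s_obs < n else float("nan"),
        "pielou": pielou(v) if s_obs >= 2 else float("nan"),
        "chao1": chao1(v),
        "ace": ace(v),
    }


def per_sample_diversity(otu_counts: pd.DataFrame) -> pd.DataFrame:
    """Diversity panel for every sample (column) of an OTU count matrix."""
    rows = {s: diversity_profile(otu_counts[s].to_numpy())
            for s in otu_counts.columns}
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return df


def group_summary(diversity: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean +- s.e.m. of each diversity estimate."""
    groups = groups.reindex(diversity.index)
    out = []
    for name, sub in diversity.groupby(groups):
        n = len(sub)
        for metric in diversity.columns:
            vals = sub[metric].dropna()
            out.append({
                "group": name, "metric": metric,
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1
                else float("nan"),
                "n": n,
            })
    return pd.DataFrame(out).set_index(["group", "metric"])
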