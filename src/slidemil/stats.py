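"""Nonparametric comparison layer for small paired samples.

Five-fold cross-validation gives only five paired observations per
comparison, so the Wilcoxon signed-rank test is computed exactly by
enumerating all 2^m sign assignments (the one-sided floor at m = 5 is
1/32 = 0.03125); the normal approximation would misstate such p-values.
Holm-Bonferroni step-down controls the family-wise error over multiple
comparisons, paired Cohen's d quantifies effect size, and the Friedman
test provides the omnibus check across aggregators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "WilcoxonResult",
    "EffectSize",
    "wilcoxon_exact",
    "holm_adjust",
    "cohens_d_paired",
    "friedman_test",
    "build_stat_report",
]


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ (sum of ranks of positive differences)
    pvalue: float


def wilcoxon_exact(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped; tied absolute differences receive average
    ranks. For m <= 15 nonzero pairs the null distribution of W+ is
    enumerated over all 2^m sign assignments, so achievable p-values lie on
    the exact lattice (the one-sided floor at m = 5 is 1/32). Beyond 15
    pairs the tie-corrected normal approximation with continuity correction
    is used. ``alternative='greater'`` tests a positive shift of x - y.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m > 15:
        mean = m * (m + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = np.sqrt(var)
        p_greater = float(norm.sf((w_plus - mean - 0.5) / sd))
        p_less = float(norm.cdf((w_plus - mean + 0.5) / sd))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_greater, p_less))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return WilcoxonResult(statistic=w_plus, pvalue=p)

    # integer DP over doubled ranks (average ranks are half-integers)
    r2 = np.round(ranks * 2).astype(int)
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        dist[r:] += dist[:-r].copy()  # copy: overlapping in-place add
    dist /= 2.0**m
    w2 = int(round(w_plus * 2))
    p_greater = float(dist[w2:].sum())
    p_less = float(dist[: w2 + 1].sum())
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(statistic=w_plus, pvalue=p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    adjusted_(i) = min(1, max_{j<=i} (m - j + 1) * p_(j)) over the ascending
    ordering; the cumulative max enforces monotonicity.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(stepped))
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass(frozen=True)
class EffectSize:
    d: float  # nan when undefined (zero spread)
    label: str  # negligible / small / medium / large / undefined


def cohens_d_paired(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Paired Cohen's d = mean(x - y) / sd(x - y), sample sd (n - 1).

    Zero difference spread is flagged as undefined rather than infinite.
    Labels follow the conventional 0.2 / 0.5 / 0.8 thresholds.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:  # identical vectors: no effect at all
            return EffectSize(d=0.0, label="negligible")
        return EffectSize(d=float("nan"), label="undefined")
    val = float(d.mean() / sd)
    a = abs(val)
    label = (
        "negligible" if a < 0.2 else "small" if a < 0.5
        else "medium" if a < 0.8 else "large"
    )
    return EffectSize(d=val, label=label)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test on a (blocks x methods) matrix.

    Ranks within each block (average ranks on ties), then
    chi2 = 12 n / (k (k + 1)) * sum_j (Rbar_j - (k + 1) / 2)^2 with k - 1 df.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 methods")
    n, k = m.shape
    ranks = np.apply_along_axis(rankdata, 1, m)
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float(((rbar - (k + 1) / 2.0) ** 2).sum())
    return stat, float(chi2.sf(stat, df=k - 1))


def build_stat_report(
    metrics: pd.DataFrame,
    reference: str,
    alternative: str = "greater",
    method_col: str = "method",
    fold_col: str = "fold",
    value_col: str = "value",
) -> dict:
    """Pairwise reference-vs-others report plus the Friedman omnibus.

    ``metrics`` is long format (method, fold, value). Returns a dict with a
    per-comparison table (delta mean, raw p, Holm-adjusted p, Cohen's d,
    effect label) and the omnibus (chi2, p).
    """
    wide = metrics.pivot(index=fold_col, columns=method_col, values=value_col)
    if reference not in wide.columns:
        raise ValueError(f"reference {reference!r} not among methods")
    others = [c for c in wide.columns if c != reference]
    ref = wide[reference].to_numpy()
    rows, raw_ps = [], []
    for other in others:
        vals = wide[other].to_numpy()
        res = wilcoxon_exact(ref, vals, alternative=alternative)
        eff = cohens_d_paired(ref, vals)
        raw_ps.append(res.pvalue)
        rows.append(
            {"comparison": f"{reference} vs. {other}",
             "delta_mean": float((ref - vals).mean()),
             "raw_p": res.pvalue, "cohens_d": eff.d, "effect": eff.label}
        )
    table = pd.DataFrame(rows)
    table.insert(3, "holm_adj_p", holm_adjust(raw_ps))
    chi2_stat, chi2_p = friedman_test(wide.to_numpy())
    return {"pairwise": table, "friedman_chi2": chi2_stat, "friedman_p": chi2_p}
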