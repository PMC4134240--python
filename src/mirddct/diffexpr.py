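"""Directional shifted-null paired tests with BH-FDR over a ddCt matrix.

For each assay the observed paired ddCt values ``d_1..d_n`` are summarized
and tested against a biologically motivated null that already concedes a
2-fold change:

* the tested direction is chosen by the sign of the median ddCt
  (negative median -> test for up-regulation, positive -> down; an exact
  zero median means no test);
* for up-regulation the hypotheses are H0: mean d >= -1 vs H1: mean d < -1
  (log2 units; 1 log2 unit = 2-fold), giving the lower-tail statistic
  ``t = (mean(d) + 1) / (SD(d)/sqrt(n))`` on n-1 degrees of freedom; the
  down-regulation test mirrors it with ``mean(d) - 1`` and the upper tail;
* p-values across all tested assays enter a Benjamini-Hochberg step-up
  at level alpha, and the realized cutoff ``(rank/m)*alpha`` is reported
  explicitly.

A per-assay normality screen (one-sample Kolmogorov-Smirnov on the
standardized residuals ``(d_i - mean d)/SD``) is advisory: failures are
flagged, never excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import Direction, fold_change

__all__ = [
    "NormalityReport",
    "DirectionalTestResult",
    "BhResult",
    "normality_screen",
    "choose_direction",
    "shifted_paired_t_test",
    "bh_correct",
    "run_differential_expression",
]


@dataclass(frozen=True)
class NormalityReport:
    """One-sample KS normality check of an assay's standardized ddCt."""

    assay_id: str
    n: int
    z_scores: Optional[np.ndarray]
    ks_d: Optional[float]
    ks_p: Optional[float]
    degenerate: bool = False


@dataclass(frozen=True)
class DirectionalTestResult:
    """Per-assay summary, directional test and fold change.

    ``t``/``df``/``p`` are ``None`` when no test was performed (median
    exactly zero, degenerate variance, or n < 2).
    """

    assay_id: str
    n: int
    mean_ddct: float
    median_ddct: float
    direction: Direction
    t: Optional[float]
    df: Optional[int]
    p: Optional[float]
    fold: float
    bh_significant: bool = False
    ks_p: Optional[float] = None


@dataclass(frozen=True)
class BhResult:
    """Benjamini-Hochberg step-up outcome with its explicit cutoff."""

    alpha: float
    m: int
    significant_ids: tuple[str, ...]
    rank: int
    cutoff: float


def normality_screen(assay_id: str, d: Sequence[float]) -> NormalityReport:
    """KS test of the standardized residuals of one assay against N(0, 1).

    Residuals are ``z_i = (d_i - mean d) / SD(d)`` with the n-1
    denominator. Zero variance yields a degenerate report with no KS
    statistic.
    """
    d = np.asarray(d, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 3:
        raise ValueError(f"normality screen needs n >= 3, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        return NormalityReport(assay_id, n, None, None, None, degenerate=True)
    z = (d - d.mean()) / sd
    ks = stats.kstest(z, "norm")
    return NormalityReport(assay_id, n, z, float(ks.statistic), float(ks.pvalue))


def choose_direction(median_ddct: float) -> Direction:
    """Regulation direction implied by the median ddCt sign.

    Negative median -> ``up`` (lower-tail test), positive -> ``down``
    (upper-tail test), exact zero -> ``none`` (no test performed).
    """
    if not np.isfinite(median_ddct):
        raise ValueError("median ddCt must be finite")
    if median_ddct < 0:
        return "up"
    if median_ddct > 0:
        return "down"
    return "none"


def shifted_paired_t_test(
    d: Sequence[float], direction: Direction, delta0: float = 1.0
) -> tuple[float, int, float]:
    """One-tailed paired t-test against a null shifted by ``delta0``.

    ``delta0`` is the log2 deregulation benchmark (default 1, i.e.
    2-fold). For ``direction='up'`` the null is mean d >= -delta0 and the
    p-value is the lower-tail probability of t; for ``'down'`` the null is
    mean d <= +delta0 and the p-value is the upper tail. Returns
    ``(t, df, p)``.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"no test for direction {direction!r}")
    d = np.asarray(d, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate variance: SD(d) = 0")
    se = sd / np.sqrt(n)
    df = n - 1
    if direction == "up":
        t = (d.mean() + delta0) / se
        p = stats.t.cdf(t, df)
    else:
        t = (d.mean() - delta0) / se
        p = stats.t.sf(t, df)
    return float(t), int(df), float(p)


def bh_correct(pvalues: Sequence[tuple[str, float]], alpha: float = 0.05) -> BhResult:
    """Benjamini-Hochberg step-up over ``(id, p)`` pairs.

    Sorts ascending, finds the largest rank i with ``p_(i) <= (i/m)*alpha``
    and declares ranks 1..i significant; the realized cutoff
    ``(i/m)*alpha`` is reported (0 when nothing passes).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("bh_correct needs at least one p-value")
    for pid, p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"p-value for {pid!r} outside (0, 1]: {p}")
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i][1])
    sorted_p = [pvalues[i][1] for i in order]
    rank = 0
    for i in range(m, 0, -1):
        if sorted_p[i - 1] <= (i / m) * alpha:
            rank = i
            break
    cutoff = (rank / m) * alpha
    significant = tuple(pvalues[order[i]][0] for i in range(rank))
    return BhResult(alpha=alpha, m=m, significant_ids=significant, rank=rank, cutoff=cutoff)


def run_differential_expression(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    delta0: float = 1.0,
    min_n: int = 2,
) -> tuple[list[DirectionalTestResult], BhResult]:
    """Full statistical pass over a pruned assay x pair ddCt matrix.

    Per assay: n, mean and median over observed cells, direction by median
    sign, shifted-null one-tailed t-test where testable, then BH across
    all tested assays (m = number actually tested). Results come back
    sorted by ascending p with untested assays last.
    """
    partial: list[dict] = []
    pvals: list[tuple[str, float]] = []
    for assay_id, row in matrix.iterrows():
        d = row.to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        if d.size == 0:
            continue
        mean_d = float(d.mean())
        median_d = float(np.median(d))
        direction = choose_direction(median_d)
        t = df = p = None
        if direction != "none" and d.size >= min_n and d.std(ddof=1) > 0:
            t, df, p = shifted_paired_t_test(d, direction, delta0)
            pvals.append((assay_id, p))
        ks_p = None
        if d.size >= 3 and d.std(ddof=1) > 0:
            ks_p = normality_screen(assay_id, d).ks_p
        fold, _ = fold_change(mean_d)
        partial.append(
            dict(
                assay_id=assay_id,
                n=int(d.size),
                mean_ddct=mean_d,
                median_ddct=median_d,
                direction=direction,
                t=t,
                df=df,
                p=p,
                fold=fold,
                ks_p=ks_p,
            )
        )
    if not pvals:
        raise ValueError("no testable assay in the matrix")
    bh = bh_correct(pvals, alpha)
    significant = set(bh.significant_ids)
    results = [
        DirectionalTestResult(bh_significant=r["assay_id"] in significant, **r)
        for r in partial
    ]
    results.sort(key=lambda r: (np.inf if r.p is None else r.p, r.assay_id))
    return results, bh
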