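"""Bland-Altman agreement on relative differences and the paired Wilcoxon test.

Bland-Altman analysis summarises paired measurements by the mean (bias) and
sample SD of per-pair relative differences, with limits of agreement at
bias +/- 1.96 SD.  Differences are expressed in percent with either the
pair mean (standard for percentage Bland-Altman) or the reference value as
denominator; the latter reads as "percent above baseline".

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
computes the exact two-sided p-value by full enumeration of the 2^n sign
assignments for small samples (n_effective <= 12 by default), falling back
to the tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

__all__ = ["LOA_MULTIPLIER", "AgreementResult", "WilcoxonResult", "bland_altman", "wilcoxon_paired"]

LOA_MULTIPLIER = 1.96  # limits of agreement at +/- 1.96 SD
EXACT_N_MAX = 12


@dataclass(frozen=True)
class AgreementResult:
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n_pairs: int
    denominator_mode: str
    diffs_pct: tuple[float, ...] = ()
    means: tuple[float, ...] = ()  # per-pair means, for agreement plots


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # signed-rank sum W (sum of ranks of positive differences)
    p_value: float
    n_effective: int
    method: str  # "exact" or "normal_approx"


def bland_altman(
    pairs: list[tuple[float, float]] | np.ndarray,
    denominator_mode: str = "pair_mean",
) -> AgreementResult:
    """Bland-Altman agreement of (test, reference) pairs on percent differences.

    Per-pair difference = 100 * (test - reference) / denominator with the
    denominator either the pair mean (default) or the reference value.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (test, reference)")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 pairs")
    test, ref = arr[:, 0], arr[:, 1]
    if np.any(ref <= 0):
        raise ValueError("reference values must be > 0")
    if denominator_mode == "pair_mean":
        denom = 0.5 * (test + ref)
    elif denominator_mode == "reference":
        denom = ref
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if np.any(denom <= 0):
        raise ValueError("non-positive denominator")
    diffs = 100.0 * (test - ref) / denom
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        bias_pct=bias,
        sd_pct=sd,
        loa_low_pct=bias - LOA_MULTIPLIER * sd,
        loa_high_pct=bias + LOA_MULTIPLIER * sd,
        n_pairs=int(arr.shape[0]),
        denominator_mode=denominator_mode,
        diffs_pct=tuple(float(v) for v in diffs),
        means=tuple(float(v) for v in 0.5 * (test + ref)),
    )


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Two-sided p by enumerating all sign assignments of the rank vector."""
    n = ranks.size
    # all 2^n subsets: bit j of row i says difference j is positive
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    w_all = bits @ ranks
    eps = 1e-9
    p_le = np.count_nonzero(w_all <= w + eps) / 2**n
    p_ge = np.count_nonzero(w_all >= w - eps) / 2**n
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original rule); |differences|
    are midranked.  Exact enumeration for n_effective <= 12, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate: no nonzero differences")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return WilcoxonResult(w, _exact_two_sided_p(ranks, w), n, "exact")
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float((counts**3 - counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    num = w - mu
    num -= 0.5 * np.sign(num)  # continuity correction
    z = num / sigma
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    return WilcoxonResult(w, min(p, 1.0), n, "normal_approx")
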