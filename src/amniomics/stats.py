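"""Small-sample statistical toolkit.

Exact Wilcoxon matched-pairs signed-rank (rank-sum distribution by dynamic
programming for n <= 25, normal approximation with tie correction above),
Kruskal-Wallis with Dunn's post-hoc on pooled mid-ranks, multiple-testing
helpers, qPCR standard-curve quantification and reporter-style ratio
normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedSample:
    values_a: np.ndarray
    values_b: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape:
            raise ValueError("paired vectors must have equal length")
        if self.values_a.size < 2:
            raise ValueError("need >= 2 pairs")
        if not (np.isfinite(self.values_a).all() and np.isfinite(self.values_b).all()):
            raise ValueError("paired values must be finite")


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Return W+ (sum of mid-ranks of positive differences) and the ranks."""
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks

def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    # Distribution of W+ over all 2^n sign assignments, by convolution on
    # doubled ranks (mid-ranks are half-integers at worst).
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    mu = total / 2.0
    dev = abs(round(w_plus * 2) - mu)
    support = np.arange(total + 1, dtype=float)
    # two-sided: mass at least as far from the null mean as observed
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    paired: PairedSample,
    zero_method: Literal["drop", "pratt"] = "drop",
) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped by default (Wilcoxon's original
    convention); ``zero_method="pratt"`` ranks them first and discards
    their ranks.  Returns ``(W+, p)``; all-zero differences give p = 1
    with a warning.
    """
    diffs = paired.values_a - paired.values_b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    if zero_method == "drop":
        diffs = diffs[diffs != 0]
        w_plus, ranks = _signed_rank_statistic(diffs)
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(diffs))
        nonzero = diffs != 0
        w_plus = float(ranks_all[(diffs > 0)].sum())
        ranks = ranks_all[nonzero]
        diffs = diffs[nonzero]
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = diffs.size
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        # normal approximation; E[W+] = sum(r)/2, Var[W+] = sum(r^2)/4
        # (mid-ranks make this the tie-corrected variance automatically)
        mu = ranks.sum() / 2.0
        sigma2 = float((ranks**2).sum()) / 4.0
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def kruskal_wallis_dunn(
    groups: Sequence[np.ndarray],
    adjust: Literal["bonferroni", "none"] = "bonferroni",
    labels: Sequence[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise post-hoc.

    Dunn's z for groups i, j uses pooled mid-ranks:

        z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)]

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Pairwise
    two-sided p-values are Bonferroni-adjusted over all pairs by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(
            "Kruskal-Wallis needs >= 3 groups; use wilcoxon_signed_rank "
            "for a two-group paired comparison"
        )
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    h_stat, p_global = sps.kruskal(*groups)

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(((tie_counts**3 - tie_counts)).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr

    rows = []
    pairs = list(combinations(range(len(groups)), 2))
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        rows.append((labels[i], labels[j], z, min(p_raw, 1.0)))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust == "bonferroni":
        table["adj_p"] = np.minimum(table["p"] * len(pairs), 1.0)
    elif adjust == "none":
        table["adj_p"] = table["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return float(h_stat), float(p_global), table


def adjust_pvalues(
    pvalues: np.ndarray, method: Literal["bonferroni", "bh", "none"]
) -> np.ndarray:
    """Multiple-testing adjustment (delegates to statsmodels)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if method == "none" or pvalues.size == 0:
        return pvalues.copy()
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(pvalues, method=sm_method)[1]


@dataclass
class QpcrRun:
    """Cycle thresholds plus a shared standard curve.

    ``standard_curve`` is a list of (log10 quantity, Ct) calibration
    points; the same fitted line converts target and housekeeping Cts
    back to quantities.
    """

    ct_target: np.ndarray
    ct_hk1: np.ndarray
    ct_hk2: np.ndarray
    standard_curve: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.ct_target = np.asarray(self.ct_target, dtype=float)
        self.ct_hk1 = np.asarray(self.ct_hk1, dtype=float)
        self.ct_hk2 = np.asarray(self.ct_hk2, dtype=float)
        if not (self.ct_target.shape == self.ct_hk1.shape == self.ct_hk2.shape):
            raise ValueError("Ct vectors must have equal length")
        curve = np.asarray(self.standard_curve, dtype=float)
        if curve.ndim != 2 or curve.shape[0] < 2:
            raise ValueError("standard curve needs >= 2 (log10 qty, Ct) points")
        if np.unique(curve[:, 0]).size < 2:
            raise ValueError("standard curve needs distinct quantities")
        for v in (self.ct_target, self.ct_hk1, self.ct_hk2):
            if not (np.isfinite(v).all() and (v > 0).all()):
                raise ValueError("Ct values must be finite and positive")


def qpcr_quantify(run: QpcrRun) -> np.ndarray:
    """Standard-curve quantification normalised to two housekeeping genes.

    Fits Ct = slope * log10(q) + intercept by least squares, inverts per
    gene, and returns target quantity / geometric mean of the two
    housekeeping quantities per sample.  A non-negative slope (quantity
    not diluting Ct upward) is rejected.
    """
    curve = np.asarray(run.standard_curve, dtype=float)
    slope, intercept = np.polyfit(curve[:, 0], curve[:, 1], 1)
    if slope >= 0:
        raise ValueError(f"invalid standard curve: slope {slope:.3g} is not negative")

    def quantity(ct: np.ndarray) -> np.ndarray:
        return 10.0 ** ((ct - intercept) / slope)

    q_target = quantity(run.ct_target)
    q_hk = np.sqrt(quantity(run.ct_hk1) * quantity(run.ct_hk2))
    return q_target / q_hk


def ratio_normalize(
    signal: np.ndarray, reference: np.ndarray, control_index: int = 0
) -> np.ndarray:
    """Reporter-style normalisation: signal/reference scaled so the
    control condition equals 1."""
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if signal.shape != reference.shape:
        raise ValueError("signal and reference must have equal length")
    if (reference <= 0).any():
        raise ValueError("reference values must be strictly positive")
    ratio = signal / reference
    control = ratio[control_index]
    if control <= 0:
        raise ValueError("control condition ratio must be positive")
    return ratio / control
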