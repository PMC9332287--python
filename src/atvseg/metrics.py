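"""Contour-agreement statistics: Dice similarity and paired Wilcoxon.

The Dice similarity coefficient between a reference volume A and a test
volume B is DSC = 2|A n B| / (|A| + |B|), ranging from 0 (disjoint) to 1
(complete overlap); an average of 0.80 is the conventional threshold for
an acceptable automatic contour.  Paired DSC scores from two segmentation
methods are compared with the Wilcoxon matched-pairs signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .image_core import BinaryMask

__all__ = [
    "DscResult",
    "WilcoxonResult",
    "DscTable",
    "dice",
    "paired_wilcoxon",
    "dsc_table",
]

#: Conventional average-DSC level for a clinically acceptable contour.
ACCEPTABLE_DSC = 0.80


@dataclass(frozen=True)
class DscResult:
    label: str
    value: float
    volume_a: int
    volume_b: int
    volume_intersection: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact" or "normal_approximation"


def dice(a: BinaryMask, b: BinaryMask) -> DscResult:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Both masks empty is a domain error (0/0) rather than a value: a silent
    1.0 or 0.0 would mask an upstream segmentation failure.
    """
    a.check_congruent(b)
    va = a.volume_voxels
    vb = b.volume_voxels
    if va + vb == 0:
        raise ValueError(
            f"DSC undefined: masks {a.label!r} and {b.label!r} are both empty"
        )
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    label = a.label if a.label == b.label else f"{a.label}|{b.label}"
    return DscResult(
        label=label,
        value=2.0 * inter / (va + vb),
        volume_a=va,
        volume_b=vb,
        volume_intersection=inter,
    )


def _signed_rank_pmf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact distribution of the positive-rank sum (on doubled ranks).

    Midranks can be half-integers, so ranks are doubled to integers and the
    distribution of W+ is built by dynamic programming over all 2^n equally
    likely sign assignments.  Entry k of the result is P(2*W+ = k).
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def paired_wilcoxon(
    x, y, exact_threshold: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Differences of exactly zero are discarded (Wilcoxon's original
    convention); |differences| are ranked with midranks for ties; the
    statistic is the smaller of the positive- and negative-rank sums.  The
    two-sided p-value is exact — P(min(W+, W-) <= observed) over all sign
    assignments — when the effective sample size is at most
    ``exact_threshold``, and otherwise uses the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1D sequences of length >= 1")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: no test possible")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    total = float(ranks.sum())  # n(n+1)/2

    if n <= exact_threshold:
        doubled = np.rint(2.0 * ranks).astype(int)
        pmf = _signed_rank_pmf(doubled)
        w2 = int(round(2.0 * w))
        s2 = int(round(2.0 * total))
        low = float(pmf[: w2 + 1].sum())
        high = float(pmf[s2 - w2:].sum())
        overlap = float(pmf[s2 - w2: w2 + 1].sum()) if w2 >= s2 - w2 else 0.0
        p = min(1.0, low + high - overlap)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
        p = min(1.0, 2.0 * norm.cdf(z))
        method = "normal_approximation"
    return WilcoxonResult(statistic=w, p_value=p, n_effective=n, method=method)


@dataclass
class DscTable:
    """Per-case DSC table for two methods plus per-organ summary.

    ``table`` mirrors the organ x method layout with one row per case and
    footer rows for the per-organ averages and Wilcoxon p-values;
    ``summary`` has one row per organ with means, the p-value (NaN when no
    test is possible because every paired difference is zero) and the
    acceptability flag (average >= 0.80).
    """

    table: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def dsc_table(
    scores: pd.DataFrame,
    case_col: str = "case",
    organ_col: str = "organ",
    method_col: str = "method",
    value_col: str = "dsc",
    exact_threshold: int = 25,
    acceptable: float = ACCEPTABLE_DSC,
) -> DscTable:
    """Summarise per-case DSC values of two methods across organs.

    ``scores`` is a long-format frame with one row per (case, organ,
    method).  Every case must carry both methods' values for every organ;
    a missing cell raises naming the case, organ and method.
    """
    methods = sorted(scores[method_col].unique())
    if len(methods) != 2:
        raise ValueError(f"expected exactly two methods, found {methods}")
    organs = list(dict.fromkeys(scores[organ_col]))
    cases = list(dict.fromkeys(scores[case_col]))

    wide = scores.pivot_table(
        index=case_col, columns=[organ_col, method_col], values=value_col,
        aggfunc="first", sort=False,
    ).reindex(cases)
    for organ in organs:
        for method in methods:
            col = (organ, method)
            if col not in wide.columns or wide[col].isna().any():
                missing = (
                    wide.index[wide[col].isna()].tolist()
                    if col in wide.columns else cases
                )
                raise ValueError(
                    f"missing DSC value for case(s) {missing}, organ {organ!r}, "
                    f"method {method!r}"
                )

    rows = []
    for organ in organs:
        a = wide[(organ, methods[0])].to_numpy()
        b = wide[(organ, methods[1])].to_numpy()
        try:
            test = paired_wilcoxon(a, b, exact_threshold=exact_threshold)
            p = test.p_value
        except ValueError:
            p = np.nan  # identical columns: no test possible
        rows.append({
            "organ": organ,
            f"mean_{methods[0]}": float(a.mean()),
            f"mean_{methods[1]}": float(b.mean()),
            "p_value": p,
            f"acceptable_{methods[0]}": bool(a.mean() >= acceptable),
            f"acceptable_{methods[1]}": bool(b.mean() >= acceptable),
        })
    summary = pd.DataFrame(rows).set_index("organ")

    footer_avg = wide.mean(axis=0).rename("Average")
    footer_p = pd.Series(
        {col: summary.loc[col[0], "p_value"] for col in wide.columns},
        name="p-value",
    )
    table = pd.concat([wide, footer_avg.to_frame().T, footer_p.to_frame().T])
    return DscTable(table=table, summary=summary)
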