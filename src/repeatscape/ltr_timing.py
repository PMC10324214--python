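"""Dating LTR retrotransposon insertions from 5'/3' LTR divergence.

The two long terminal repeats of an LTR retrotransposon are identical at
the moment of insertion and subsequently diverge neutrally, so their
divergence dates the insertion.  The pipeline is: global alignment of the
two LTRs, raw proportion of differing sites ``p`` (gap and N columns
excluded), Jukes-Cantor multiple-hit correction
``k = -(3/4) ln(1 - 4p/3)``, and insertion age ``T = k / (2 r)`` with a
neutral substitution rate ``r`` per site per year (default 1.38e-8).
The factor 2 reflects that both LTRs accumulate substitutions
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_RATE",
    "InsertionTimeEstimate",
    "align_pair",
    "p_distance",
    "jc69_distance",
    "insertion_time",
    "estimate_insertion_times",
    "age_histogram",
]

#: Neutral substitution rate per site per year used by default.
DEFAULT_RATE = 1.38e-8

_GAP_SCORE = -2
_MATCH_SCORE = 1
_MISMATCH_SCORE = -1


@dataclass(frozen=True)
class InsertionTimeEstimate:
    element_id: str
    p: float
    k: float
    r: float
    T: float


def align_pair(
    seq_a: str,
    seq_b: str,
    match: int = _MATCH_SCORE,
    mismatch: int = _MISMATCH_SCORE,
    gap: int = _GAP_SCORE,
) -> tuple[str, str]:
    """Global (end-to-end) alignment with linear gap penalties.

    Needleman-Wunsch with a deterministic traceback: on score ties the
    diagonal move is preferred, then the vertical (gap in ``seq_b``), then
    the horizontal.  Returns the two gapped sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    cols = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match, mismatch)
        cand = np.maximum(score[i - 1, :-1] + sub, score[i - 1, 1:] + gap)
        # with a linear gap, chains of horizontal moves give
        # score[i, j] = gap*j + max(score[i, 0], max_{k<=j}(cand[k-1] - gap*k)),
        # a prefix maximum computable in one accumulate pass
        prefix = np.maximum.accumulate(
            np.concatenate(([score[i, 0]], cand - gap * cols))
        )
        score[i, 1:] = prefix[1:] + gap * cols
    # traceback, diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and s == score[i - 1, j] + gap:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Raw proportion of differing sites over comparable columns.

    Columns containing a gap or an N in either sequence are excluded from
    both numerator and denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    comparable = 0
    diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-N" or y in "-N":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable (non-gap, non-N) columns")
    return diffs / comparable


def jc69_distance(p: float) -> float:
    """Jukes-Cantor corrected divergence ``k = -(3/4) ln(1 - 4p/3)``.

    Valid for ``0 <= p < 0.75``; beyond that the correction is undefined
    (saturated divergence).
    """
    if p < 0:
        raise ValueError("p must be nonnegative")
    if p >= 0.75:
        raise ValueError(f"saturated divergence: p = {p} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def insertion_time(k: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in years, ``T = k / (2 r)``."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if k < 0:
        raise ValueError("divergence must be nonnegative")
    return k / (2.0 * r)


def estimate_insertion_times(
    pairs: Sequence[tuple[str, str, str]],
    r: float = DEFAULT_RATE,
) -> list[InsertionTimeEstimate]:
    """Full dating pipeline for ``(element_id, ltr5, ltr3)`` tuples."""
    estimates = []
    for element_id, ltr5, ltr3 in pairs:
        aln = align_pair(ltr5, ltr3)
        p = p_distance(*aln)
        k = jc69_distance(p)
        estimates.append(
            InsertionTimeEstimate(element_id=element_id, p=p, k=k, r=r, T=insertion_time(k, r))
        )
    return estimates


def age_histogram(
    estimates: Sequence[InsertionTimeEstimate],
    bin_width_my: float = 0.5,
) -> pd.DataFrame:
    """Insertion-abundance profile: element counts in age bins of
    ``bin_width_my`` million years."""
    if bin_width_my <= 0:
        raise ValueError("bin width must be positive")
    ages_my = np.array([e.T / 1e6 for e in estimates])
    if ages_my.size == 0:
        return pd.DataFrame(columns=["age_bin_lo_my", "age_bin_hi_my", "count"])
    n_bins = int(np.floor(ages_my.max() / bin_width_my)) + 1
    edges = np.arange(n_bins + 1) * bin_width_my
    counts, _ = np.histogram(ages_my, bins=edges)
    return pd.DataFrame(
        {
            "age_bin_lo_my": edges[:-1],
            "age_bin_hi_my": edges[1:],
            "count": counts,
        }
    )


def estimates_to_frame(estimates: Sequence[InsertionTimeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": e.element_id,
                "p": e.p,
                "k": e.k,
                "r": e.r,
                "T_years": e.T,
            }
            for e in estimates
        ],
        columns=["element_id", "p", "k", "r", "T_years"],
    )
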