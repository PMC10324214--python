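"""Transposable-element statistics: subclass classification, genome-coverage
totals, divergence landscapes with shape classification, and community
diversity indices.

A *divergence landscape* is a histogram of genome coverage by TE copies,
binned by percent divergence of each copy from its family consensus.  Low
divergence indicates recent insertions, so the landscape is a proxy for the
age structure of TE activity: an "L-shaped" landscape (single peak at <= 5%
divergence) indicates a recent burst, while bimodal or multi-peaked
landscapes indicate repeated waves of accumulation together with retention
of ancient copies.

Diversity of the TE community is summarised by Simpson's index
``D = 1 - sum n_i (n_i - 1) / (N (N - 1))`` and the Shannon index
``H = -sum p_i ln p_i``, where ``n_i`` is the number of base pairs occupied
by subclass *i*, ``N = sum n_i``, and ``p_i = n_i / N``.  By default the
community is assessed at the four-subclass level (LINE, SINE, LTR, DNA
transposons), each subclass playing the role of a "species" in the
ecological analogy.
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_formats import RepeatRecord

__all__ = [
    "TESubclass",
    "DivergenceLandscape",
    "LandscapeShape",
    "ShapeLabel",
    "DiversityProfile",
    "classify_te",
    "compute_te_totals",
    "compute_landscape",
    "classify_landscape_shape",
    "simpson_index",
    "shannon_index",
    "diversity_profile",
    "DIVERSITY_SUBCLASSES",
]


class TESubclass(Enum):
    LINE = "LINE"
    SINE = "SINE"
    LTR = "LTR"
    DNA = "DNA"
    ROLLING_CIRCLE = "RC"
    SATELLITE = "Satellite"
    SIMPLE = "Simple_repeat"
    LOW_COMPLEXITY = "Low_complexity"
    UNKNOWN = "Unknown"
    OTHER = "Other"


#: The four subclasses entering the diversity indices by default.
DIVERSITY_SUBCLASSES = (
    TESubclass.LINE,
    TESubclass.SINE,
    TESubclass.LTR,
    TESubclass.DNA,
)

_CLASS_MAP = {
    "LINE": TESubclass.LINE,
    "SINE": TESubclass.SINE,
    "LTR": TESubclass.LTR,
    "DNA": TESubclass.DNA,
    "RC": TESubclass.ROLLING_CIRCLE,
    "SATELLITE": TESubclass.SATELLITE,
    "SIMPLE_REPEAT": TESubclass.SIMPLE,
    "LOW_COMPLEXITY": TESubclass.LOW_COMPLEXITY,
    "UNKNOWN": TESubclass.UNKNOWN,
    "UNSPECIFIED": TESubclass.UNKNOWN,
}


def classify_te(class_family: str) -> TESubclass:
    """Map a raw RepeatMasker class/family string onto a subclass.

    The token before "/" decides; a trailing "?" (uncertain classification)
    is stripped before matching.  The function is total: unrecognised
    tokens map to ``OTHER``.
    """
    token = class_family.split("/")[0].strip().rstrip("?")
    return _CLASS_MAP.get(token.upper(), TESubclass.OTHER)


def compute_te_totals(
    records: Iterable[RepeatRecord],
    genome_length: int,
    merge_overlaps: bool = False,
) -> pd.DataFrame:
    """Per-subclass occupied bp and percent of genome.

    In the default mode each record contributes its full aligned span
    (``q_end - q_begin + 1``); with ``merge_overlaps`` overlapping records
    of the same subclass on the same sequence are counted once.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    bp: dict[TESubclass, int] = {sub: 0 for sub in TESubclass}
    if merge_overlaps:
        by_key: dict[tuple[TESubclass, str], list[tuple[int, int]]] = {}
        for r in records:
            _check_extent(r, genome_length)
            by_key.setdefault((classify_te(r.class_family), r.query_id), []).append(
                (r.q_begin, r.q_end)
            )
        for (sub, _), ivals in by_key.items():
            from .genome_partition import merge_intervals

            bp[sub] += sum(e - s + 1 for s, e in merge_intervals(ivals))
    else:
        for r in records:
            _check_extent(r, genome_length)
            bp[classify_te(r.class_family)] += r.span
    rows = [
        {
            "subclass": sub.name,
            "bp": bp[sub],
            "pct_of_genome": 100.0 * bp[sub] / genome_length,
        }
        for sub in TESubclass
    ]
    return pd.DataFrame(rows)


def _check_extent(r: RepeatRecord, genome_length: int) -> None:
    if r.q_end > genome_length:
        raise ValueError(
            f"record {r.record_id} extends to {r.q_end} beyond genome "
            f"length {genome_length}"
        )


@dataclass
class DivergenceLandscape:
    """Genome-coverage histogram over divergence bins, per TE subclass.

    ``coverage`` is a (n_bins x n_subclasses) matrix of percent-of-genome
    values; bin *i* covers divergences in the half-open interval
    ``[i * bin_width, (i + 1) * bin_width)``.  Records at or beyond
    ``max_div`` are dropped and counted in ``n_dropped``.
    """

    bin_edges: np.ndarray
    subclasses: tuple[TESubclass, ...]
    coverage: np.ndarray
    genome_length: int
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def total_per_bin(self) -> np.ndarray:
        """Summed coverage over subclasses, one value per divergence bin."""
        return self.coverage.sum(axis=1)

    def subclass_total(self, sub: TESubclass) -> float:
        return float(self.coverage[:, self.subclasses.index(sub)].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coverage, columns=[s.name for s in self.subclasses]
        )
        df.insert(0, "div_bin_lo", self.bin_edges[:-1])
        df.insert(1, "div_bin_hi", self.bin_edges[1:])
        return df


def compute_landscape(
    records: Iterable[RepeatRecord],
    genome_length: int,
    max_div: float = 50.0,
    bin_width: float = 1.0,
) -> DivergenceLandscape:
    """Bin TE coverage by percent divergence from consensus.

    Each record contributes its aligned bp to bin
    ``floor(pct_div / bin_width)`` of its subclass.  Coverage is expressed
    as percent of ``genome_length``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_bins = max_div / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide max_div")
    n_bins = int(round(n_bins))
    subclasses = tuple(TESubclass)
    cov_bp = np.zeros((n_bins, len(subclasses)), dtype=float)
    col = {sub: j for j, sub in enumerate(subclasses)}
    dropped = 0
    for r in records:
        if r.pct_div >= max_div:
            dropped += 1
            continue
        b = int(r.pct_div // bin_width)
        cov_bp[b, col[classify_te(r.class_family)]] += r.span
    return DivergenceLandscape(
        bin_edges=np.arange(n_bins + 1) * bin_width,
        subclasses=subclasses,
        coverage=100.0 * cov_bp / genome_length,
        genome_length=genome_length,
        n_dropped=dropped,
    )


class ShapeLabel(Enum):
    L_SHAPED = "L_SHAPED"
    BIMODAL = "BIMODAL"
    MULTI_PEAKED = "MULTI_PEAKED"
    UNIMODAL_OLD = "UNIMODAL_OLD"


@dataclass(frozen=True)
class LandscapeShape:
    label: ShapeLabel
    detected_peak_bins: tuple[int, ...]


def classify_landscape_shape(
    landscape: DivergenceLandscape,
    smoothing_window: int = 3,
    prominence_fraction: float = 0.2,
) -> LandscapeShape:
    """Classify a landscape's age structure from its peak positions.

    The total-coverage-per-bin series is smoothed by a centred moving
    average, and peaks are local maxima whose smoothed height is at least
    ``prominence_fraction`` of the global smoothed maximum.  One peak at a
    divergence bin <= 5 is L-shaped (recent burst); one peak beyond 5 is a
    unimodal-old landscape; two peaks, bimodal; more, multi-peaked.
    Boundary bins can be peaks.
    """
    total = landscape.total_per_bin()
    if not np.any(total > 0):
        raise ValueError("no coverage: cannot classify an all-zero landscape")
    smoothed = _centered_moving_average(total, smoothing_window)
    # pad below zero so maxima at the first/last bin register as peaks
    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    height = prominence_fraction * smoothed.max()
    peaks, _ = find_peaks(padded, height=height)
    peak_bins = tuple(int(p - 1) for p in peaks)
    if len(peak_bins) == 1:
        label = (
            ShapeLabel.L_SHAPED if peak_bins[0] <= 5 else ShapeLabel.UNIMODAL_OLD
        )
    elif len(peak_bins) == 2:
        label = ShapeLabel.BIMODAL
    else:
        label = ShapeLabel.MULTI_PEAKED
    return LandscapeShape(label=label, detected_peak_bins=peak_bins)


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    if window == 1:
        return x.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sums / counts


# ---------------------------------------------------------------------------
# Diversity indices


def simpson_index(n_by_subclass: Mapping | Sequence[float]) -> float:
    """Simpson's diversity index ``D = 1 - sum n(n-1) / (N(N-1))``.

    ``n`` are occupied-bp counts per subclass; ``N`` is their sum.  ``D``
    is the probability that two TE base pairs drawn without replacement
    belong to different subclasses.
    """
    counts = _as_counts(n_by_subclass)
    total = counts.sum()
    if total < 2:
        raise ValueError("Simpson index undefined for N < 2")
    return float(1.0 - np.sum(counts * (counts - 1)) / (total * (total - 1)))


def shannon_index(n_by_subclass: Mapping | Sequence[float]) -> float:
    """Shannon diversity ``H = -sum p_i ln p_i`` over subclass proportions."""
    counts = _as_counts(n_by_subclass)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for N = 0")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def _as_counts(n_by_subclass: Mapping | Sequence[float]) -> np.ndarray:
    if isinstance(n_by_subclass, Mapping):
        values = list(n_by_subclass.values())
    else:
        values = list(n_by_subclass)
    counts = np.asarray(values, dtype=float)
    if np.any(counts < 0):
        raise ValueError("subclass counts must be nonnegative")
    return counts


@dataclass(frozen=True)
class DiversityProfile:
    n_by_subclass: dict[str, int]
    total_bp: int
    simpson: float
    shannon: float


def diversity_profile(
    records: Iterable[RepeatRecord],
    subclasses: Sequence[TESubclass] = DIVERSITY_SUBCLASSES,
) -> DiversityProfile:
    """Diversity of the TE community occupied by the given subclasses.

    By default only LINE, SINE, LTR and DNA transposons enter the indices;
    rolling-circle elements, satellites and simple/low-complexity repeats
    are reported in totals but excluded here.
    """
    keep = set(subclasses)
    bp: dict[TESubclass, int] = {sub: 0 for sub in subclasses}
    for r in records:
        sub = classify_te(r.class_family)
        if sub in keep:
            bp[sub] += r.span
    counts = {sub.name: n for sub, n in bp.items()}
    total = sum(counts.values())
    return DiversityProfile(
        n_by_subclass=counts,
        total_bp=total,
        simpson=simpson_index(list(counts.values())),
        shannon=shannon_index(list(counts.values())),
    )
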