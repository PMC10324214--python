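"""Microsatellite (SSR) detection and summary statistics.

Detects perfect SSRs (P-SSRs: exact tandem repeats of a primitive 1-6 bp
motif) and imperfect SSRs (I-SSRs: tandem tracts interrupted by a small
number of mismatches or indels), standardizes motifs to a canonical form,
and computes per-genome relative abundance (loci per Mb of valid, non-N
length) and relative density (bp per Mb of valid length).

Perfect detection reports maximal non-extendable tandem runs, including a
trailing partial repeat unit, so ``repeats`` may be fractional.  A run
whose motif is a tandem of a shorter motif is always reported at the
shorter period ("ATATATAT" is 4 x "AT", never 2 x "ATAT").  Runs
containing N are excluded, and reported loci are non-overlapping,
chosen leftmost-first.

Imperfect detection is a greedy seed-and-extend: perfect runs meeting loose
seed thresholds are extended left and right, permitting mismatches and
single-base indels, while a running alignment score (match +1, mismatch -1,
gap -2) stays positive and no more than ``max_consecutive_edits``
consecutive edited positions occur; a locus is reported when its final
score reaches ``min_score`` and it contains at least one edit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence

__all__ = [
    "SSRKind",
    "SSRLocus",
    "SSRSummary",
    "standardize_motif",
    "find_perfect_ssrs",
    "find_imperfect_ssrs",
    "summarize_ssrs",
    "DEFAULT_MIN_REPEATS",
]

#: Minimum repeat counts for mono- through hexanucleotide motifs.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_SIZE_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


class SSRKind(Enum):
    PERFECT = "PERFECT"
    IMPERFECT = "IMPERFECT"


@dataclass(frozen=True)
class SSRLocus:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    standard_motif: str
    repeats: float
    kind: SSRKind
    edits: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def standardize_motif(motif: str) -> str:
    """Canonical form of a motif: the lexicographically smallest string
    among all cyclic rotations of the motif and of its reverse complement.

    This groups motifs that describe the same tandem tract read from either
    strand or in any phase ("GT", "TG", "AC" and "CA" all map to "AC").
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {len(motif)}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(motif))
    ]
    return min(candidates)


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a tandem of a shorter motif."""
    return motif not in (motif + motif)[1:-1]


def find_perfect_ssrs(
    seq: GenomeSequence,
    min_repeats: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """Detect perfect microsatellites as maximal tandem runs.

    For each period ``m`` in 1..6, a run is a maximal stretch where every
    base equals the base ``m`` positions earlier.  Runs with an
    N anywhere in their span are excluded, non-primitive motifs are skipped
    (they are found at their shorter period), and candidate loci across
    periods are made non-overlapping by greedy leftmost-first selection
    (ties broken toward the shorter motif).
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    for m, k in min_repeats.items():
        if m > 1 and k < 2:
            raise ValueError("min repeats must be >= 2 for motif length > 1")
    s = seq.residues
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    not_n = arr != ord("N")
    candidates: list[SSRLocus] = []
    for m in sorted(min_repeats):
        if n < 2 * m:
            continue
        eq = (arr[:-m] == arr[m:]) & not_n[:-m] & not_n[m:]
        # maximal True-blocks of eq correspond to maximal period-m runs
        boundaries = np.diff(eq.astype(np.int8))
        starts = list(np.nonzero(boundaries == 1)[0] + 1)
        ends = list(np.nonzero(boundaries == -1)[0] + 1)
        if eq.size and eq[0]:
            starts.insert(0, 0)
        if eq.size and eq[-1]:
            ends.append(eq.size)
        for i0, i1 in zip(starts, ends):
            span = (i1 - i0) + m  # run occupies s[i0 : i1 + m]
            repeats = span / m
            if repeats < min_repeats[m]:
                continue
            motif = s[i0 : i0 + m]
            if not _is_primitive(motif):
                continue
            candidates.append(
                SSRLocus(
                    seq_id=seq.id,
                    start=i0 + 1,
                    end=i0 + span,
                    motif=motif,
                    standard_motif=standardize_motif(motif),
                    repeats=repeats,
                    kind=SSRKind.PERFECT,
                    edits=0,
                )
            )
    candidates.sort(key=lambda loc: (loc.start, len(loc.motif)))
    selected: list[SSRLocus] = []
    last_end = 0
    for loc in candidates:
        if loc.start > last_end:
            selected.append(loc)
            last_end = loc.end
    return selected


# ---------------------------------------------------------------------------
# Imperfect SSRs


@dataclass(frozen=True)
class _ExtensionParams:
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    max_consecutive_edits: int = 2


def _extend(
    s: str,
    pos: int,
    phase: int,
    motif: str,
    score: int,
    params: _ExtensionParams,
    direction: int,
) -> tuple[int, int, int]:
    """Greedily extend a tandem tract from ``pos`` in ``direction``.

    ``phase`` is the index into ``motif`` expected at ``pos``.  Returns the
    position one past the last base of the best (maximum-score) extension,
    the score there, and the number of edits used.  Extension stops when
    the running score would drop to zero, when more than
    ``max_consecutive_edits`` consecutive edited positions would be
    needed, or at an N or the end of the sequence.
    """
    m = len(motif)
    n = len(s)
    best_pos, best_score, best_edits = pos, score, 0
    edits = 0
    consecutive = 0
    lookahead = 3

    def matches_ahead(p: int, ph: int) -> int:
        cnt = 0
        for k in range(lookahead):
            q = p + direction * k
            if not (0 <= q < n) or s[q] == "N":
                break
            if s[q] != motif[(ph + direction * k) % m]:
                break
            cnt += 1
        return cnt

    while 0 <= pos < n and s[pos] != "N":
        expected = motif[phase % m]
        if s[pos] == expected:
            score += params.match
            consecutive = 0
            pos += direction
            phase += direction
            if score > best_score:
                best_pos, best_score, best_edits = pos, score, edits
            continue
        # choose among mismatch / insertion (extra base in sequence) /
        # deletion (missing base) by short lookahead; prefer the cheaper
        # mismatch on ties
        nxt = pos + direction
        mm = matches_ahead(nxt, phase + direction)
        ins = matches_ahead(nxt, phase)
        dele = matches_ahead(pos, phase + direction)
        best_op = max(mm, ins, dele)
        if best_op == 0:
            break
        if consecutive + 1 > params.max_consecutive_edits:
            break
        if mm == best_op:
            delta, dp, dph = params.mismatch, direction, direction
        elif dele == best_op:
            delta, dp, dph = params.gap, 0, direction
        else:
            delta, dp, dph = params.gap, direction, 0
        if score + delta <= 0:
            break
        score += delta
        edits += 1
        consecutive += 1
        pos += dp
        phase += dph
    return best_pos, best_score, best_edits


def find_imperfect_ssrs(
    seq: GenomeSequence,
    seed_min_repeats: int = 3,
    seed_min_length: int = 8,
    max_consecutive_edits: int = 2,
    min_score: int = 12,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> list[SSRLocus]:
    """Detect imperfect microsatellites by greedy seed-and-extend.

    Seeds are perfect tandem runs with at least ``seed_min_repeats`` units
    and ``seed_min_length`` bp (they may fall below the perfect-SSR
    reporting thresholds).  Tracts that are fully perfect are excluded:
    those belong to :func:`find_perfect_ssrs` output only.
    """
    params = _ExtensionParams(match, mismatch, gap, max_consecutive_edits)
    seed_thresholds = {
        m: max(seed_min_repeats, -(-seed_min_length // m)) for m in range(1, 7)
    }
    seeds = find_perfect_ssrs(seq, min_repeats=seed_thresholds)
    s = seq.residues
    loci: list[SSRLocus] = []
    last_end = 0  # 1-based end of last reported locus
    for seed in seeds:
        if seed.start <= last_end:
            continue
        motif = seed.motif
        m = len(motif)
        seed_len = seed.length
        # extend right from one past the seed
        right0 = seed.start - 1 + seed_len  # 0-based position after seed
        r_pos, r_score, r_edits = _extend(
            s, right0, seed_len % m, motif, seed_len, params, +1
        )
        # extend left from just before the seed
        l_pos, l_score, l_edits = _extend(
            s, seed.start - 2, -1 % m, motif, r_score, params, -1
        )
        start0 = l_pos + 1  # _extend returns one past the last base
        end0 = r_pos - 1
        final_score = l_score
        edits = r_edits + l_edits
        if edits == 0:
            continue  # fully explained as perfect
        if final_score < min_score:
            continue
        length = end0 - start0 + 1
        loci.append(
            SSRLocus(
                seq_id=seq.id,
                start=start0 + 1,
                end=end0 + 1,
                motif=motif,
                standard_motif=standardize_motif(motif),
                repeats=length / m,
                kind=SSRKind.IMPERFECT,
                edits=edits,
            )
        )
        last_end = end0 + 1
    return loci


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class SSRSummary:
    table: pd.DataFrame  # one row per motif-size class plus "all"

    def row(self, size_class: str) -> pd.Series:
        return self.table.set_index("size_class").loc[size_class]


def summarize_ssrs(loci: Sequence[SSRLocus], valid_length: int) -> SSRSummary:
    """Per-size-class and overall abundance/density statistics.

    relative_abundance: loci per Mb of valid (non-N) length;
    relative_density: SSR bp per Mb of valid length;
    pct_of_genome: percent of valid length covered by SSRs.
    """
    if valid_length <= 0:
        raise ValueError("valid_length must be positive")
    mb = valid_length / 1e6
    rows = []
    for size in range(1, 7):
        sub = [loc for loc in loci if len(loc.motif) == size]
        rows.append(_summary_row(_SIZE_CLASS[size], sub, mb, valid_length))
    rows.append(_summary_row("all", list(loci), mb, valid_length))
    return SSRSummary(table=pd.DataFrame(rows))


def _summary_row(name: str, loci: list[SSRLocus], mb: float, valid_length: int) -> dict:
    total_bp = sum(loc.length for loc in loci)
    return {
        "size_class": name,
        "locus_count": len(loci),
        "total_bp": total_bp,
        "relative_abundance": len(loci) / mb,
        "relative_density": total_bp / mb,
        "pct_of_genome": 100.0 * total_bp / valid_length,
    }


def loci_to_frame(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": loc.seq_id,
                "start": loc.start,
                "end": loc.end,
                "motif": loc.motif,
                "standard_motif": loc.standard_motif,
                "repeats": loc.repeats,
                "kind": loc.kind.value,
                "edits": loc.edits,
            }
            for loc in loci
        ],
        columns=[
            "seq_id",
            "start",
            "end",
            "motif",
            "standard_motif",
            "repeats",
            "kind",
            "edits",
        ],
    )
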