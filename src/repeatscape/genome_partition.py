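"""Partition genomes into exonic, intronic and intergenic territory.

Territory is computed from GFF3 gene models with 1-based inclusive
intervals: genic territory is the union of gene spans, exonic territory the
union of exon spans (clipped to genic), intronic territory is genic minus
exonic, and intergenic territory is everything else.  Introns are
enumerated per gene as the gaps between the merged union of that gene's
exons, so alternative isoforms never double-count intronic bp.  Assembly
gaps (runs of N of at least ``gap_min_run`` bp) are intersected with the
intronic and intergenic territories to give the two gap tallies.

The partition satisfies the exact conservation law
``exon_bp + intron_bp + intergenic_bp = genome_length``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GenomeSequence, GffFeature

__all__ = ["GenomePartition", "merge_intervals", "partition_genome"]

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals; adjacent intervals coalesce.

    ``[(1, 10), (11, 20)]`` merges to ``[(1, 20)]`` because base 10 and
    base 11 are contiguous.
    """
    ivals = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivals:
        if start > end:
            raise ValueError(f"invalid interval ({start}, {end}): start > end")
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _total_bp(intervals: Sequence[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def _complement(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Complement of disjoint sorted intervals within [1, length]."""
    out: list[Interval] = []
    cursor = 1
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= length:
        out.append((cursor, length))
    return out


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _n_runs(seq: GenomeSequence, min_run: int) -> list[Interval]:
    return [
        (m.start() + 1, m.end())
        for m in re.finditer(f"N{{{min_run},}}", seq.residues)
    ]


@dataclass(frozen=True)
class GenomePartition:
    genome_length: int
    exon_bp: int
    intron_bp: int
    intergenic_bp: int
    intronic_gap_bp: int
    intergenic_gap_bp: int
    exon_count: int
    intron_count: int
    mean_exon_len: float
    mean_intron_len: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def partition_genome(
    features: Iterable[GffFeature],
    genomes: Sequence[GenomeSequence],
    gap_min_run: int = 10,
) -> GenomePartition:
    """Partition a genome into exon/intron/intergenic territory.

    ``features`` is a full GFF3 feature list; ``gene`` rows are
    authoritative for genic territory (``mRNA`` spans are used only when no
    gene rows exist).  Exons are attached to their gene through the
    ID/Parent chain.  Overlapping genes are merged for territory but
    introns are enumerated per gene.  Mean lengths for empty categories
    are reported as 0 with count 0.
    """
    feats = list(features)
    seq_len = {g.id: g.length for g in genomes}
    genome_length = sum(seq_len.values())

    gene_types = {"gene"}
    genes = [f for f in feats if f.feature_type in gene_types]
    if not genes:
        genes = [f for f in feats if f.feature_type == "mRNA"]
    gene_ids = {f.attributes.get("ID") for f in genes if f.attributes.get("ID")}

    # parent chain: transcript ID -> gene ID
    tx_to_gene: dict[str, str] = {}
    for f in feats:
        fid = f.attributes.get("ID")
        parent = f.attributes.get("Parent")
        if fid and parent and parent in gene_ids:
            tx_to_gene[fid] = parent

    gene_by_id = {f.attributes.get("ID"): f for f in genes}
    exons_by_gene: dict[str, list[GffFeature]] = {gid: [] for gid in gene_ids}
    for f in feats:
        if f.feature_type != "exon":
            continue
        parent = f.attributes.get("Parent")
        if parent in gene_ids:
            gid = parent
        elif parent in tx_to_gene:
            gid = tx_to_gene[parent]
        else:
            raise ValueError(
                f"exon at {f.seq_id}:{f.start}-{f.end} has unresolvable "
                f"Parent {parent!r}"
            )
        gene = gene_by_id[gid]
        if f.seq_id != gene.seq_id or f.start < gene.start or f.end > gene.end:
            raise ValueError(f"exon outside span of its gene {gid!r}")
        exons_by_gene[gid].append(f)

    for f in genes:
        if f.seq_id not in seq_len:
            raise ValueError(f"gene on unknown sequence {f.seq_id!r}")
        if f.end > seq_len[f.seq_id]:
            raise ValueError(
                f"gene {f.attributes.get('ID', '?')!r} extends beyond "
                f"sequence {f.seq_id!r}"
            )

    exon_bp = intron_bp = intergenic_bp = 0
    intronic_gap_bp = intergenic_gap_bp = 0
    exon_count = intron_count = 0
    exon_total_len = intron_total_len = 0

    for seq in genomes:
        seq_genes = [f for f in genes if f.seq_id == seq.id]
        genic = merge_intervals([(f.start, f.end) for f in seq_genes])
        exon_ivals: list[Interval] = []
        for f in seq_genes:
            gid = f.attributes.get("ID")
            gene_exons = merge_intervals(
                [(e.start, e.end) for e in exons_by_gene.get(gid, [])]
            )
            exon_ivals.extend(gene_exons)
            # per-gene intron enumeration: gaps between merged exons
            for (s1, e1), (s2, _) in zip(gene_exons, gene_exons[1:]):
                intron_count += 1
                intron_total_len += s2 - e1 - 1
            exon_count += len(gene_exons)
            exon_total_len += _total_bp(gene_exons)
        exonic = _intersect(merge_intervals(exon_ivals), genic)
        intronic = _intersect(_complement(exonic, seq.length), genic)
        intergenic = _complement(genic, seq.length)

        exon_bp += _total_bp(exonic)
        intron_bp += _total_bp(intronic)
        intergenic_bp += _total_bp(intergenic)

        gaps = _n_runs(seq, gap_min_run)
        intronic_gap_bp += _total_bp(_intersect(gaps, intronic))
        intergenic_gap_bp += _total_bp(_intersect(gaps, intergenic))

    return GenomePartition(
        genome_length=genome_length,
        exon_bp=exon_bp,
        intron_bp=intron_bp,
        intergenic_bp=intergenic_bp,
        intronic_gap_bp=intronic_gap_bp,
        intergenic_gap_bp=intergenic_gap_bp,
        exon_count=exon_count,
        intron_count=intron_count,
        mean_exon_len=exon_total_len / exon_count if exon_count else 0.0,
        mean_intron_len=intron_total_len / intron_count if intron_count else 0.0,
    )
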