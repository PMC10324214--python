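"""Readers and writers for the standard formats the pipeline consumes.

All genomic intervals are 1-based and inclusive on both ends, matching the
conventions of RepeatMasker ``.out`` files and GFF3.  Any half-open
arithmetic is confined to private helpers in downstream modules.

Soft-masked (lowercase) residues are accepted on input and uppercased;
masking state is not retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GenomeSequence",
    "RepeatRecord",
    "GffFeature",
    "read_fasta",
    "write_fasta",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "read_tsv",
    "write_tsv",
    "read_habitat_table",
]

_VALID_RESIDUES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A nucleotide sequence with its N-aware length bookkeeping.

    ``valid_length`` (the number of non-N residues) is the denominator used
    for SSR abundance and density statistics.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = re.search(f"[^{''.join(sorted(_VALID_RESIDUES))}]", self.residues)
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residue {bad.group()!r} "
                f"at position {bad.start() + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def valid_length(self) -> int:
        return self.length - self.residues.count("N")


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker annotation row.

    ``pct_div`` is the percent divergence of the genomic copy from its
    family consensus — the x-axis of repeat landscapes.  Coordinates are
    1-based inclusive on the query sequence.
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_id: str
    q_begin: int
    q_end: int
    strand: str
    repeat_name: str
    class_family: str
    record_id: int

    def __post_init__(self) -> None:
        if self.q_begin > self.q_end:
            raise ValueError(
                f"repeat record {self.record_id}: q_begin {self.q_begin} > "
                f"q_end {self.q_end}"
            )
        if self.pct_div < 0:
            raise ValueError(f"repeat record {self.record_id}: negative divergence")

    @property
    def span(self) -> int:
        """Aligned length on the query, in bp."""
        return self.q_end - self.q_begin + 1


@dataclass(frozen=True)
class GffFeature:
    seq_id: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.attributes.get('ID', '?')}: start > end"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Wrapped lines are concatenated, lowercase residues are uppercased.
    Residues outside A/C/G/T/N (including IUPAC ambiguity codes) are
    rejected with the offending position.
    """
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(GenomeSequence(name, "".join(chunks)))
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}: sequence data before first header (line {lineno})"
                    )
                chunks.append(line)
    if name is not None:
        records.append(GenomeSequence(name, "".join(chunks)))
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The two header lines and the blank separator are skipped.  The strand
    column value ``C`` (complement) is normalised to ``-``.  Parenthesised
    "(left)" columns are validated but not retained as coordinates.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if fields[0] in ("SW", "score"):  # header lines
                continue
            if len(fields) not in (15, 16):
                raise ValueError(
                    f"{path}:{lineno}: expected 15 or 16 columns, got {len(fields)}"
                )
            try:
                sw = int(fields[0])
                div, dele, ins = (float(x) for x in fields[1:4])
                q_begin, q_end = int(fields[5]), int(fields[6])
                rec_id = int(fields[14])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from None
            strand = fields[8]
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {fields[8]!r}")
            records.append(
                RepeatRecord(
                    sw_score=sw,
                    pct_div=div,
                    pct_del=dele,
                    pct_ins=ins,
                    query_id=fields[4],
                    q_begin=q_begin,
                    q_end=q_end,
                    strand=strand,
                    repeat_name=fields[9],
                    class_family=fields[10],
                    record_id=rec_id,
                )
            )
    return records


def write_repeatmasker_out(records: Iterable[RepeatRecord], path: str | Path) -> None:
    """Write records in the standard ``.out`` column layout (with header)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for r in records:
            strand = "C" if r.strand == "-" else "+"
            fh.write(
                f"{r.sw_score:>5} {r.pct_div:>5.1f} {r.pct_del:>4.1f} "
                f"{r.pct_ins:>4.1f}  {r.query_id:<10} {r.q_begin:>8} "
                f"{r.q_end:>8} (0)  {strand}  {r.repeat_name:<15} "
                f"{r.class_family:<20} 1 {r.span} (0) {r.record_id}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Read a 9-column GFF3 file; comment and directive lines are skipped."""
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from None
            attrs: dict[str, str] = {}
            for item in cols[8].split(";"):
                item = item.strip()
                if not item:
                    continue
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            feats.append(
                GffFeature(
                    seq_id=cols[0],
                    source=cols[1],
                    feature_type=cols[2],
                    start=start,
                    end=end,
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attributes=attrs,
                )
            )
    return feats


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.seq_id}\t{f.source}\t{f.feature_type}\t{f.start}\t{f.end}\t"
                f"{f.score}\t{f.strand}\t{f.phase}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path, require_branch_lengths: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree.

    When ``require_branch_lengths`` is set (as it is for trees destined for
    ancestral-state reconstruction), any non-root edge without a length is
    an error.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if require_branch_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                label = edge.head_node.taxon.label if edge.head_node.taxon else "internal node"
                raise ValueError(f"missing branch length above {label}")
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Tables


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with a header row and deterministic column order."""
    table.to_csv(path, sep="\t", index=False)


def read_habitat_table(path: str | Path) -> pd.DataFrame:
    """Read a species/habitat table: one row per (species, habitat_type) pair."""
    df = read_tsv(path)
    missing = {"species", "habitat_type"} - set(df.columns)
    if missing:
        raise ValueError(f"habitat table missing columns: {sorted(missing)}")
    return df
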