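"""Synthetic genomes, LTR pairs, trees and trait panels with known truth.

Every downstream stage of the pipeline can be exercised on data generated
here, with a truth table recording exactly what was planted where.  The
generator is deliberately idealised: planted features never overlap, TE
copies diverge from their consensus by independent per-site substitutions
with no indels (so the realised divergence of a copy is exactly its
proportion of changed sites), and the background is i.i.d. nucleotides at
a configurable GC content.  These simplifications keep the planted truth
exact and the expected statistics analytically predictable.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; the same configuration always yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, GffFeature, RepeatRecord

__all__ = [
    "TEPlan",
    "SSRPlan",
    "GenePlan",
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_ltr_pairs",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_species_panel",
    "panel_habitat_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_HABITAT_VOCABULARY = (
    "Forest",
    "Wetlands",
    "Grassland",
    "Savanna",
    "Shrubland",
    "Desert",
    "Rocky areas",
    "Artificial",
)


@dataclass(frozen=True)
class TEPlan:
    """A cohort of TE copies from one consensus at one target divergence."""

    consensus_id: str
    subclass: str  # raw class/family string, e.g. "LINE/L1"
    copy_count: int
    target_divergence: float  # percent, expectation of realised divergence
    consensus_length: int = 1000


@dataclass(frozen=True)
class SSRPlan:
    motif: str
    repeats: int
    edits: int = 0  # substitutions planted inside the tract


@dataclass(frozen=True)
class GenePlan:
    exon_count: int
    exon_len: int
    intron_len: int


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome_length: int
    gc_content: float = 0.4
    te_plan: tuple[TEPlan, ...] = ()
    ssr_plan: tuple[SSRPlan, ...] = ()
    gene_plan: tuple[GenePlan, ...] = ()
    gap_plan: tuple[int, ...] = ()
    sequence_id: str = "chr1"


@dataclass(frozen=True)
class SimulatedGenome:
    genome: GenomeSequence
    repeats: list[RepeatRecord]
    genes: list[GffFeature]
    truth: pd.DataFrame  # one row per planted feature


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Substitute each site with probability ``rate`` to a uniformly chosen
    different base.  Returns the mutated copy and the realised count."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out, len(hits)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Emit a genome with planted TE copies, SSR tracts, gene models and
    N-gaps, together with matching annotations and a truth table.

    Features are placed in plan order, separated by background runs of at
    least 1 bp whose total is multinomially distributed over the slots.
    The bases flanking an SSR tract are forced to break the tandem, so the
    planted coordinates are exactly the maximal run.
    """
    rng = np.random.default_rng(config.seed)
    features: list[dict] = []  # seq (np.uint8 array) + metadata

    # --- TE copies
    rec_id = 0
    for plan in config.te_plan:
        consensus = _random_bases(rng, plan.consensus_length, config.gc_content)
        for c in range(plan.copy_count):
            copy, hits = _mutate(rng, consensus, plan.target_divergence / 100.0)
            realized = round(100.0 * hits / plan.consensus_length, 1)
            rec_id += 1
            features.append(
                {
                    "type": "TE",
                    "seq": copy,
                    "name": f"{plan.consensus_id}#{c + 1}",
                    "subclass": plan.subclass,
                    "divergence": realized,
                    "record_id": rec_id,
                }
            )

    # --- SSR tracts
    for si, plan in enumerate(config.ssr_plan, 1):
        motif = plan.motif.upper()
        tract = np.frombuffer((motif * plan.repeats).encode(), dtype=np.uint8)
        edit_positions = _spread_edit_positions(plan, len(motif), len(tract))
        tract = tract.copy()
        for pos in edit_positions:
            choices = _BASES[_BASES != tract[pos]]
            tract[pos] = choices[rng.integers(3)]
        features.append(
            {
                "type": "SSR",
                "seq": tract,
                "name": f"ssr{si}",
                "motif": motif,
                "edits": plan.edits,
            }
        )

    # --- gene models (exon/intron sequence is plain background)
    for gi, plan in enumerate(config.gene_plan, 1):
        glen = plan.exon_count * plan.exon_len + (plan.exon_count - 1) * plan.intron_len
        features.append(
            {
                "type": "GENE",
                "seq": _random_bases(rng, glen, config.gc_content),
                "name": f"gene{gi}",
                "plan": plan,
            }
        )

    # --- assembly gaps
    for ni, run in enumerate(config.gap_plan, 1):
        features.append(
            {
                "type": "GAP",
                "seq": np.full(run, ord("N"), dtype=np.uint8),
                "name": f"gap{ni}",
            }
        )

    total = sum(len(f["seq"]) for f in features)
    n = len(features)
    min_spacer = 2 * _FLANK_WINDOW  # room for both neighbours' flank windows
    cumulative = 0
    for i, f in enumerate(features):
        cumulative += len(f["seq"])
        if cumulative + min_spacer * (i + 2) > config.genome_length:
            raise ValueError(
                f"infeasible plan: feature {f['name']!r} does not fit in "
                f"genome_length {config.genome_length}"
            )
    slack = config.genome_length - total - min_spacer * (n + 1)
    spacers = min_spacer + rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))

    genome = np.empty(config.genome_length, dtype=np.uint8)
    cursor = 0
    placed: list[tuple[dict, int, int]] = []  # (feature, start0, end0) 0-based
    for i, f in enumerate(features):
        pad = int(spacers[i])
        genome[cursor : cursor + pad] = _random_bases(rng, pad, config.gc_content)
        cursor += pad
        genome[cursor : cursor + len(f["seq"])] = f["seq"]
        placed.append((f, cursor, cursor + len(f["seq"]) - 1))
        cursor += len(f["seq"])
    pad = config.genome_length - cursor
    genome[cursor:] = _random_bases(rng, pad, config.gc_content)

    for f, s0, e0 in placed:
        if f["type"] == "SSR":
            _break_tandem_flanks(rng, genome, s0, e0, f["motif"])

    residues = genome.tobytes().decode()
    seq = GenomeSequence(config.sequence_id, residues)

    repeats: list[RepeatRecord] = []
    genes: list[GffFeature] = []
    truth_rows: list[dict] = []
    for f, s0, e0 in placed:
        start, end = s0 + 1, e0 + 1
        row = {
            "feature_id": f["name"],
            "type": f["type"],
            "seq_id": config.sequence_id,
            "start": start,
            "end": end,
            "subclass": f.get("subclass", ""),
            "motif": f.get("motif", ""),
            "true_divergence_pct": f.get("divergence", np.nan),
            "true_edits": f.get("edits", 0),
            "sequence": genome[s0 : e0 + 1].tobytes().decode(),
        }
        truth_rows.append(row)
        if f["type"] == "TE":
            repeats.append(
                RepeatRecord(
                    sw_score=e0 - s0 + 1,
                    pct_div=f["divergence"],
                    pct_del=0.0,
                    pct_ins=0.0,
                    query_id=config.sequence_id,
                    q_begin=start,
                    q_end=end,
                    strand="+",
                    repeat_name=f["name"],
                    class_family=f["subclass"],
                    record_id=f["record_id"],
                )
            )
        elif f["type"] == "GENE":
            genes.extend(_gene_features(config.sequence_id, f["name"], f["plan"], start))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "feature_id",
            "type",
            "seq_id",
            "start",
            "end",
            "subclass",
            "motif",
            "true_divergence_pct",
            "true_edits",
            "sequence",
        ],
    )
    return SimulatedGenome(genome=seq, repeats=repeats, genes=genes, truth=truth)


def _spread_edit_positions(plan: SSRPlan, m: int, tract_len: int) -> list[int]:
    """Interior, well-separated substitution positions for an I-SSR tract.

    Edits avoid the first and last motif unit and sit at least one unit
    apart, so the tract's boundaries stay exact matches."""
    if plan.edits == 0:
        return []
    lo, hi = m, tract_len - m - 1
    if hi < lo:
        raise ValueError(f"SSR tract {plan.motif}x{plan.repeats} too short for edits")
    positions = np.linspace(lo, hi, num=plan.edits + 2)[1:-1]
    out = sorted({int(round(p)) for p in positions})
    if len(out) != plan.edits or any(
        b - a <= m for a, b in zip(out, out[1:])
    ):
        raise ValueError(
            f"cannot place {plan.edits} well-separated edits in "
            f"{plan.motif}x{plan.repeats}"
        )
    return out


#: bases rewritten on each side of a planted SSR so that no extension —
#: perfect or mismatch/indel-tolerant — can continue past the tract.
_FLANK_WINDOW = 4


def _break_tandem_flanks(
    rng: np.random.Generator, genome: np.ndarray, s0: int, e0: int, motif: str
) -> None:
    """Make the planted tract exactly maximal.

    Each flanking base within the window is chosen to differ from the
    motif continuation at its own phase and at the two neighbouring
    phases, so neither a direct match nor a single-indel rephasing can
    extend the tract."""
    m = len(motif)
    span = e0 - s0 + 1
    for j in range(_FLANK_WINDOW):
        right = e0 + 1 + j
        if right < len(genome):
            forbidden = {ord(motif[(span + j + d) % m]) for d in (-1, 0, 1)}
            genome[right] = _choose_allowed(rng, forbidden)
        left = s0 - 1 - j
        if left >= 0:
            forbidden = {ord(motif[(-j - 1 + d) % m]) for d in (-1, 0, 1)}
            genome[left] = _choose_allowed(rng, forbidden)


def _choose_allowed(rng: np.random.Generator, forbidden: set[int]) -> int:
    choices = np.array([b for b in _BASES if int(b) not in forbidden])
    return int(choices[rng.integers(len(choices))])


def _gene_features(
    seq_id: str, gene_id: str, plan: GenePlan, start: int
) -> list[GffFeature]:
    glen = plan.exon_count * plan.exon_len + (plan.exon_count - 1) * plan.intron_len
    end = start + glen - 1
    feats = [
        GffFeature(seq_id, "sim", "gene", start, end, ".", "+", ".", {"ID": gene_id}),
        GffFeature(
            seq_id, "sim", "mRNA", start, end, ".", "+", ".",
            {"ID": f"{gene_id}.t1", "Parent": gene_id},
        ),
    ]
    pos = start
    for e in range(plan.exon_count):
        feats.append(
            GffFeature(
                seq_id, "sim", "exon", pos, pos + plan.exon_len - 1, ".", "+", ".",
                {"ID": f"{gene_id}.t1.e{e + 1}", "Parent": f"{gene_id}.t1"},
            )
        )
        pos += plan.exon_len + plan.intron_len
    return feats


# ---------------------------------------------------------------------------
# LTR pairs


def simulate_ltr_pairs(
    n: int,
    ages: Sequence[float],
    rate: float = 1.38e-8,
    consensus_length: int = 1000,
    seed: int = 0,
) -> list[tuple[str, str, float]]:
    """Simulate 5'/3' LTR pairs that have diverged for the given ages.

    Each member of a pair evolves independently from the ancestral LTR for
    ``age`` years under the Jukes-Cantor process: a site differs from the
    ancestor with probability ``(3/4)(1 - exp(-4 d / 3))`` where
    ``d = rate * age``, and a changed site is uniform over the other three
    bases.  The expected pairwise JC-corrected divergence is therefore
    ``2 * rate * age``, matching the dating formula ``T = k / (2 r)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ages = list(ages)
    if len(ages) == 1:
        ages = ages * n
    if len(ages) != n:
        raise ValueError("ages must have length 1 or n")
    if any(a < 0 for a in ages):
        raise ValueError("ages must be nonnegative")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, float]] = []
    for age in ages:
        ancestor = _random_bases(rng, consensus_length, 0.5)
        d = rate * age
        p_site = 0.75 * -np.expm1(-4.0 * d / 3.0)
        ltrs = []
        for _ in range(2):
            copy = ancestor.copy()
            hits = np.nonzero(rng.random(consensus_length) < p_site)[0]
            for i in hits:
                choices = _BASES[_BASES != copy[i]]
                copy[i] = choices[rng.integers(3)]
            ltrs.append(copy.tobytes().decode())
        pairs.append((ltrs[0], ltrs[1], float(age)))
    return pairs


# ---------------------------------------------------------------------------
# Trees and traits


def simulate_tree(n_tips: int, seed: int = 0, labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Random rooted ultrametric tree via a Kingman-style coalescent.

    Pairs of lineages merge in random order at exponentially distributed
    intervals; branch lengths are in arbitrary time-proportional units.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    lineages = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        node.age_tmp = 0.0
        lineages.append(node)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += float(rng.exponential(2.0 / (k * (k - 1))))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age_tmp = t
        a, b = lineages[i], lineages[j]
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = t - child.age_tmp
        lineages = [x for x in lineages if x is not a and x is not b] + [parent]
    tree.seed_node = lineages[0]
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    root_state: float,
    sigma2: float,
    seed: int = 0,
) -> dict[str, float]:
    """Evolve a continuous trait along the tree under Brownian motion.

    Increments along each branch are independent Gaussian with variance
    ``sigma2 * branch_length``.  Returns tip label -> trait value.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): float(root_state)}
    traits: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if id(node) not in values:  # non-root: draw increment from parent
            bl = float(node.edge.length or 0.0)
            parent_val = values[id(node.parent_node)]
            values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            traits[node.taxon.label] = values[id(node)]
    return traits


# ---------------------------------------------------------------------------
# Species panel


def simulate_species_panel(
    n_species: int = 14,
    seed: int = 0,
    r2_target: float = 0.9,
    size_range_gb: tuple[float, float] = (1.1, 6.8),
) -> pd.DataFrame:
    """A species panel with genome sizes and linearly related repeat totals.

    Genome sizes are uniform on ``size_range_gb`` (defaults span the range
    of published anuran assemblies).  Repeat bp grows linearly with genome
    size (roughly one-third of the smallest genomes to two-thirds of the
    largest are repeats), with Gaussian noise scaled so the population R^2
    of the size-vs-repeat regression equals ``r2_target``.  SSR counts and
    bp follow the same construction at microsatellite scale.  Habitats are
    1-5 types drawn per species from a fixed vocabulary.
    """
    if n_species < 2:
        raise ValueError("panel regression needs at least 2 species")
    if not 0 < r2_target <= 1:
        raise ValueError("r2_target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = size_range_gb
    sizes = rng.uniform(lo, hi, n_species)
    sd_x = (hi - lo) / np.sqrt(12.0)

    def linear_with_noise(slope: float, intercept: float) -> np.ndarray:
        y = intercept + slope * sizes
        if r2_target < 1:
            noise_sd = abs(slope) * sd_x * np.sqrt((1 - r2_target) / r2_target)
            y = y + rng.normal(0.0, noise_sd, n_species)
        return y

    repeat_bp = linear_with_noise(0.69e9, -0.39e9).clip(min=0.0)
    ssr_count = linear_with_noise(0.5e6, 0.2e6).clip(min=0.0)
    ssr_bp = linear_with_noise(0.03e9, 0.005e9).clip(min=0.0)
    habitats = [
        ",".join(
            sorted(
                rng.choice(
                    _HABITAT_VOCABULARY, size=int(rng.integers(1, 6)), replace=False
                )
            )
        )
        for _ in range(n_species)
    ]
    return pd.DataFrame(
        {
            "species": [f"sp{i + 1:02d}" for i in range(n_species)],
            "genome_size": sizes,
            "repeat_bp": repeat_bp,
            "ssr_count": np.round(ssr_count).astype(int),
            "ssr_bp": np.round(ssr_bp).astype(int),
            "habitats": habitats,
        }
    )


def panel_habitat_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Explode the panel's habitat column into (species, habitat_type) rows."""
    rows = [
        {"species": r.species, "habitat_type": h}
        for r in panel.itertuples()
        for h in str(r.habitats).split(",")
        if h
    ]
    return pd.DataFrame(rows, columns=["species", "habitat_type"])
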