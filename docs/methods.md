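# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package, in the spirit of a methods supplement: what
each stage assumes, which knobs matter, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates and formats

All genomic intervals are 1-based and inclusive on both ends, the shared
convention of RepeatMasker `.out` and GFF3; half-open arithmetic is
confined to private helpers. Soft-masked (lowercase) residues are
uppercased on input and masking state is discarded — no downstream
statistic uses it. FASTA parsing rejects IUPAC ambiguity codes other than
N, reporting the offending position, because every downstream denominator
("valid length") assumes a strict A/C/G/T/N alphabet. Habitat tables are
TSV with one `(species, habitat_type)` row per pair — the minimal lossless
layout for niche-width counting.

## TE classification and landscapes

`classify_te` keys on the token before `/` in the RepeatMasker
class/family string, after stripping a trailing `?` (RepeatMasker's
uncertainty marker). The function is total; unrecognised tokens fall into
`OTHER` so that totals always conserve input bp.

`compute_landscape` bins each annotation's aligned span into
`floor(pct_div / bin_width)` with default 1%-wide bins from 0 to 50%.
Records at or beyond the 50% ceiling are dropped and counted, never
silently discarded; the conservation identity

```
Σ_bins coverage(subclass) = totals(subclass) − dropped(subclass)
```

is property-tested. Overlapping annotations are *not* resolved in the
default totals (each record contributes its full span); a `merge_overlaps`
mode counts overlapping same-subclass intervals once. The divergence
column of the `.out` file is used directly as the age axis; CpG-adjusted
distances recomputed from `.align` files are out of scope.

Shape classification smooths the summed per-bin coverage with a centred
moving average (window 3 bins, odd by construction; edges renormalised)
and calls peaks as local maxima with height at least 20% of the global
smoothed maximum; boundary bins are eligible (the series is padded below
zero), since an L-shaped landscape typically peaks in bin 0–2. One peak at
bin ≤ 5 ⇒ L-shaped; one peak above ⇒ unimodal-old; two ⇒ bimodal; more ⇒
multi-peaked. Window and prominence are exposed because shape calls on
real landscapes are traditionally made by eye; the defaults reproduce the
planted-cohort truth reliably (see below) but are not sacred.

## Diversity indices

Simpson's `D = 1 − Σ nᵢ(nᵢ−1)/(N(N−1))` requires count semantics for the
`n(n−1)` term, so `nᵢ` are occupied base-pair counts per subclass and `N`
their sum (`D` is then exactly the probability that two TE base pairs
drawn without replacement belong to different subclasses — verified
against a resampling oracle). Descriptions of these inputs as
"proportions" circulate in the comparative literature but are incompatible
with the finite-sample formula; with bp-scale counts `D` is numerically
indistinguishable from the proportion-based `1 − Σ pᵢ²`. Diversity is
assessed at the four-subclass level (LINE, SINE, LTR, DNA transposons);
rolling-circle elements, satellites and simple/low-complexity repeats are
reported in totals but excluded from the community by default.

## SSR scanning

Perfect SSRs are maximal runs where every base equals the base `m`
positions earlier (`m` = motif length 1–6), including a trailing partial
unit, so `repeats` may be fractional. Motifs must be primitive; a tandem
of a shorter motif is always reported at the shorter period. Runs touching
N are excluded. Reported loci are made non-overlapping greedily,
leftmost-first with ties to the shorter motif. Default minimum repeats
(12, 7, 5, 4, 4, 4 for mono→hexa) follow the common default of
genome-scale SSR scanners and are fully configurable. The scanner is
checked for exact equality against an independent regex-enumeration oracle
over all primitive motifs.

Imperfect SSRs use greedy seed-and-extend: perfect seeds of ≥ 3 units and
≥ 8 bp are extended in both directions, classifying each interruption as
mismatch, insertion or deletion by a 3-base lookahead (ties prefer the
cheaper mismatch), while the running score (+1 match, −1 mismatch, −2 gap)
stays positive and at most 2 consecutive edited positions occur; the locus
is trimmed back to its maximum-score extent and reported if the final
score reaches 12 and it contains at least one edit. Tracts that are fully
perfect are never emitted as imperfect. The exact parameterisation of
published SSR tools is not documented at this level of detail, so this
algorithm is fixed here with every constant config-exposed; reported loci
are validated by independent re-scoring. Compound SSRs (adjacent tracts of
different motifs) are deliberately not merged or reported.

Relative abundance (loci/Mb) and density (bp/Mb) use the *valid* (non-N)
length as denominator. Per-Mb units are the field convention; a raw
fraction against valid length would put abundance at the 10⁻⁵ scale and is
monotone-equivalent.

## LTR insertion dating

The dating chain is alignment → `p` → JC69 → `T = k/(2r)`. The global
alignment is Needleman–Wunsch with match +1, mismatch −1, linear gap −2,
and a deterministic traceback (diagonal, then up, then left on ties); the
implementation is row-vectorised with a prefix-maximum trick for the
horizontal chains and is verified against an exhaustive-recursion oracle.
Columns containing a gap or N are excluded from both numerator and
denominator of `p` — whether published `k` values excluded indel columns
is rarely stated; exclusion is the conservative choice for a
substitutions-only clock. `k = −(3/4)ln(1 − 4p/3)` is defined for
`p < 0.75`; saturated pairs are an error, not a clipped value. The default
neutral rate is `r = 1.38 × 10⁻⁸` per site per year; `T` is linear in `k`
and inversely linear in `r`, so any other rate is a rescaling. Age
histograms default to 0.5-My bins, with "recent" conventionally < 1 My.
Structural discovery of intact elements (LTRharvest-style) is out of
scope: the module consumes paired-LTR FASTA (suffixes `_5`/`_3`) or a
precomputed `k` table.

## Genome partitioning

Genic territory is the union of `gene` spans (`mRNA` spans only when no
gene rows exist); exonic is the union of exons clipped to genic; intronic
is genic minus exonic; intergenic is the rest. This yields the exact
conservation law `exon + intron + intergenic = genome length` on every
input, which is property-tested on random annotations. Introns are
enumerated per gene from the merged union of that gene's exons across
isoforms, so alternative transcripts never double-count intronic bp; mean
lengths come from this enumeration, and overlapping genes are merged for
territory but enumerated separately. Assembly gaps are runs of ≥ 10 N
(configurable — "gap" has no universal minimum run length) intersected
with intronic/intergenic territory. Empty categories report mean 0 with
count 0 rather than NaN.

## Brownian-motion ancestral states

Under BM, tip and node states are jointly Gaussian with covariance equal
to shared root-to-node path length times the rate σ². The node estimate is
the conditional expectation given the tips, computed by re-rooting the
tree at the node and recursively collapsing each neighbouring subtree to a
`(mean, variance-length)` message: a tip contributes `(x, branch)`, an
internal node the precision-weighted mean of its messages plus its own
branch. Polytomies are handled natively — no random resolution. The
estimate is independent of σ²; variances are
`σ̂² × (Σᵢ 1/vᵢ)⁻¹` at the re-rooted node, which equals the GLS-prediction
(universal kriging) variance from the full covariance matrix (verified
numerically), and `σ̂²` is the ML rate `(x−â)ᵀC⁻¹(x−â)/n`, accumulated in
one pruning pass. Node estimates are checked to 10⁻⁸ against a
brute-force multivariate-normal conditioning oracle on random trees.
Zero-length internal branches are rejected with a suggestion to collapse
them; the weights are undefined there. Reconstruction is exactly
location/scale equivariant, so units (Gb, %) are a display choice.

## Regressions and habitat

All correlations are plain OLS of each metric against genome size, with
R², the two-sided slope test (identical to the F test in simple
regression) and residual SE. Phylogenetically corrected regression (PGLS)
is deliberately not used in v1 — the correlate batteries this mirrors are
ordinary least squares — and is a natural extension. Metrics with fewer
than 3 non-missing species are skipped with a warning. Niche width is the
number of distinct habitat types per species (duplicates deduplicated);
species absent from the habitat table carry no information and are
excluded and listed, not imputed as zero.

## Synthetic data: what it emulates and what it does not

The generator plants TE copies, SSR tracts, gene models and N-gap runs
into an i.i.d. background at configurable GC, never overlapping, with a
truth table of exact coordinates. Design choices that keep truth exact:

* TE copies mutate i.i.d. per site to a uniformly chosen different base —
  no indels — so realised divergence equals the fraction of changed sites
  and is written to the emitted `.out` as-is (rounded to 0.1, the format's
  precision). A cohort of 100 copies × 1 kb at target 10% has a realised
  cohort mean within ±1 percentage point (binomial SE ≈ 0.095).
* SSR tracts are written with a 4-bp "anti-motif" window on each flank
  (every flank base differs from the motif continuation at its own and
  both neighbouring phases), so planted coordinates are exactly the
  maximal run for the perfect scanner *and* un-extendable by the
  mismatch/indel-tolerant imperfect scanner. Features are separated by at
  least 8 bp of background so flank windows never collide.
* Planted imperfect tracts place substitutions in the interior, at least
  one unit apart, keeping boundary units intact.
* LTR pairs evolve by exact JC endpoint sampling: each site differs from
  the ancestor with probability `(3/4)(1 − e^(−4rt/3))`, changed bases
  uniform over the other three. This makes `E[k̂] = 2rt` exactly, so the
  `T = k/(2r)` estimator is unbiased by construction rather than only to
  first order in `rt`.
* BM traits accumulate independent Gaussian increments of variance
  `σ²·branch` down the tree; trees come from a seeded Kingman-style
  coalescent (random pair merges at exponential intervals).
* The species panel draws genome sizes uniform on 1.1–6.8 Gb (the span of
  published anuran assemblies) and builds repeat totals as
  `repeat_gb ≈ −0.39 + 0.69·size_gb` plus Gaussian noise — anchor points
  chosen so repeats run from about a third of the smallest genomes to
  about two-thirds of the largest. Noise SD is solved from the target
  population R² (default 0.9): `σ = |b|·SD(x)·√((1−R²)/R²)`.

What passing on this generator does **not** show: robustness to TE
nesting/fragmentation and indel evolution, soft-masking artefacts,
assembly errors, chromosome-scale memory behaviour, or real divergence
landscapes' overdispersion relative to the binomial (CpG hypermutability,
rate variation among copies). Landscape-shape recovery in particular needs
adequately powered cohorts: with 100 copies × 1 kb per cohort the planted
3%/30% structure classifies as bimodal in 60/60 random seeds, whereas
small cohorts (tens of copies of a few hundred bp) produce genuinely
jagged old-age peaks that the 20%-prominence rule correctly reports as
multi-peaked. Problem sizes used by the test suite and the acceptance
script (5-kb sequences for scanner–oracle equivalence, 200 LTR pairs of
1 kb, 400–1000 BM replicates on 10-tip trees, 14-species panels) were
chosen to make sampling error small relative to the tested tolerances.

## Numerical and degenerate-input conventions

Empty FASTA → empty list; header-only `.out` → empty record list; no
genes → everything intergenic with zero-count means 0; Simpson needs
N ≥ 2, Shannon N > 0; `p ≥ 0.75` is saturated divergence (error);
constant-x or n < 3 regressions are errors, constant-y gives R² = 0 with
p = 1. All randomness flows from integer seeds through
`numpy.random.default_rng`; outputs are byte-identical across runs and
platform-independent (integer-state RNG, no locale or time dependence).
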