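# Methods

This note documents the models, conventions and numerical choices behind
`msatmine`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic-data tests do and do not show
about real data.

## Repeat model

A microsatellite allele is modelled as a *perfect* tandem array of a
2–4 bp unit. Interrupted or compound repeats are out of scope: perfection
makes allele length identically `unit_count × unit_length`, which is what
fragment analysis measures, and keeps every downstream length comparison
exact. Units that are whole-number repetitions of a shorter unit
(homopolymers, `ATAT`) are invalid motifs — they would otherwise create
duplicate representations of the same array. Each unit is reduced to a
canonical class representative: the lexicographic minimum over all cyclic
rotations of the unit and of its reverse complement. This makes `(AC)n`,
`(CA)n` and `(GT)n` hits indistinguishable, as they must be for
strand-agnostic clustering.

The scanner reports maximal arrays with at least `min_units = 4` full
units. Four is deliberately lenient: the biologically motivated `≥ 6`
units rule is applied later as an explicit exclusion filter, so that the
filter report shows *why* a locus was dropped rather than silently never
seeing it. Trailing partial units belong to the flank
(`end − start = unit_count × unit_length` always); a consequence is that
coordinates under reverse complementation mirror only up to a sub-unit
phase shift, which the tests account for. Overlapping candidate
representations resolve leftmost-longest (longer array wins, then smaller
start, then shorter unit). `N` never matches and truncates arrays.
Coordinates are 0-based half-open everywhere.

## Locus clustering from unassembled reads

With no reference genome, two hits come from the same locus exactly when
their flanking sequences agree. Each hit is first flipped into a canonical
orientation. The orientation key compares the flanks *read outward from
the repeat boundary* (right flank vs reverse-complemented left flank,
truncated to their common length), keeping the orientation with the
smaller key and breaking ties toward the as-read orientation. The outward
comparison matters: reads truncate flanks at different depths, and any
rule that compares flank ends distant from the repeat (e.g. concatenating
whole flanks) orients reads of one locus inconsistently and splits the
locus into strand-specific clusters — we observed exactly that failure
before settling on the outward rule.

Clustering then joins hits that share (a) the canonical motif, (b) an
exactly matching anchor k-mer — the `anchor_k = 12` flank bases
immediately adjoining the repeat — on at least one side, and (c) at most
`max_mismatch = 2` substitutions over the full overlapping flank regions.
Union-find transitive closure makes the result independent of read order
and strand. Hits with a flank shorter than `min_flank = 20` bp are set
aside as unclusterable. The exact-anchor-then-tolerant design gives an
O(n·bucket) search with an explicit, testable matching criterion.

Allele length is the array span in bp, read only from members whose array
is fully contained with at least one flank base on both sides; a repeat
touching a read end has unknowable length and contributes to clustering
only. Alleles need `min_support = 2` reads — with only ~4 chromosomes
sampled, a single supporting read is indistinguishable from a sequencing
error. A cluster is polymorphic with ≥ 2 surviving alleles. Allele lengths
are not forced to motif-length multiples, but non-multiple spacing raises
a warning flag on the cluster (an indel-in-flank signature). Consensus
flanks are per-column majority votes aligned at the repeat boundary, ties
to the lexicographically smallest base for determinism.

## Exclusion filters

All rules report together (a reason *set*), so the report shows every
defect of a locus:

- `TOO_FEW_REPEATS`: longest allele under 6 tandem units — short arrays
  mutate too slowly and score poorly.
- `BROAD_RANGE`: allele span over `max_allele_range_bp = 20` bp
  (configurable; the quantification of "too broad to score reliably").
- `REPETITIVE`: either flank exceeds a DUST-like low-complexity score
  (sum of C(c,2) over triplet counts per window, normalised by window
  triplet count − 1; window 36, threshold 1.5 — a perfect 4-mer repeat
  scores ≈ 3.9, random sequence ≈ 0.3), or an anchor k-mer recurs in more
  than `max_shared_anchor_clusters = 2` clusters (a multi-copy signal that
  needs no repeat library).
- `CONTAMINANT_LIKE`: ungapped seed-and-extend local identity ≥ 0.90 over
  ≥ 30 bp against a user-supplied contaminant FASTA (12-mer seeds, X-drop
  extension, both strands). Generic by design: the same screen serves a
  human check and cross-species checks. With no index supplied the check
  is *skipped with a logged warning*, never silently passed.
- `FLANKS_TOO_SHORT`: consensus flanks cannot host a primer.

Tightening any threshold can only shrink the passing set (tested).

## Primer design

Degraded fecal DNA is the motivating constraint: every product, for the
*largest* allele, must fit `max_amplicon_bp = 150` including both primers,
whose lengths are 18–22 bp each and 36–44 bp combined. Further
constraints: GC in [0.40, 0.60], Tm in [54, 62] °C with |ΔTm| ≤ 3 °C, no
homopolymer of 5, a 3′ G/C clamp with at most 3 G/C in the last five
bases, and primers never overlap the repeat array. All bounds live in
`DesignConstraints`, not in code. Enumeration is exhaustive over both
flanks; ranking is deterministic (|ΔTm|, then product size, then
position). An empty result records `NO_PRIMERS` on the locus.

Melting temperatures: Wallace rule `2(A+T) + 4(G+C)`, or a
nearest-neighbor model with the unified dinucleotide table (SantaLucia
1998), entropic salt correction `0.368 (N−1) ln[Na⁺]` at 50 mM Na⁺, and
`Tm = ΔH / (ΔS' + R ln(Ct/4))` at 250 nM per-strand concentration. The
implementation is in-package with its parameters in config; the test
suite cross-checks it against an independent implementation and against a
hand-summed ΔH/ΔS oracle.

The 18 bp M13 forward tail (`TGTAAAACGACGGCCAGT`) participates **only** in
reported size ranges (+18 bp per product) — the genomic primer is what
binds, so specificity search never sees the tail.

## In-silico PCR

A primer binds where its Hamming distance to the template window is
≤ `max_mismatch = 2` *and* its 3′-most `three_prime_exact = 3` bases match
exactly (extension requires a matched 3′ end). Substitutions only — no
indels — which keeps a naive all-pairs enumeration oracle exact. Products
are all facing site pairs on opposite strands within
`max_product` (1000 bp for validation, so off-target geometries are seen;
150 bp is the design-time cap). Classification from per-template product
sizes: `no_product`; `multiple_products` if a template yields extra
products outside one expected-size window (two in-window products are a
heterozygote's two alleles, not secondary bands; with no window declared,
any multi-product template qualifies); `broad_range` if the size spread
exceeds the cap; `monomorphic` if all templates agree on one size;
`single_product_polymorphic` otherwise.

## Panel statistics

Estimators operate per locus on complete observations (pairwise deletion),
matching standard population-genetics software behaviour. `H_E` is
reported plain (`1 − Σpᵢ²`) and with the unbiased `2n/(2n−1)` correction;
reconstructions of published marker rows match only under the corrected
form, so panel reports display it. `P_ID` and `P_ID(sib)` use the Waits
et al. (2001) equations on sample frequencies without small-sample
correction. `F_IS` comes in both the simple `1 − H_O/H_E` form and the
Weir & Cockerham (1984) single-population f from per-allele variance
components (`b = n/(n−1)[p(1−p) − (2n−1)/(4n) h̄]`, `c = h̄/2`,
`f = 1 − Σc/Σ(b+c)`); published multi-allele rows are consistent with the
variance-component form. F_IS at a monomorphic locus is an explicit
undefined signal, never 0.

Cumulative panel power sorts loci ascending by the chosen per-locus
probability (ties by locus id), multiplies, and reports the first count
whose running product is strictly below the threshold (sentinel if never).
Display rounding is half-up to 2 decimals; internal arithmetic is full
precision.

Concordance between paired tables (e.g. blood vs fecal) classifies each
shared call as match, allelic dropout (A heterozygous, B homozygous for
one of A's alleles), false allele (B carries an allele absent from A), or
other mismatch. A call hit by both dropout and a false allele presents as
false allele, so the dropout estimator divides the raw per-heterozygote
dropout fraction by (1 − false-allele rate); both estimators then recover
the simulated rates in closed loop.

## Synthetic data: what it emulates, what it does not

The generator mirrors the target study design: 2 diploid individuals
(4 chromosomes), 30 kb haplotype genomes with 24 planted loci (75%
polymorphic, alleles 8–13 units with up to 2 units of spread), 80 bp
unique flanks, 300 bp reads at 30× per haplotype, substitution-only read
errors. Bases abutting each planted array are resampled so the array can
never extend into the flank — planted allele length therefore equals the
maximal-array span exactly, which is what makes exact-length recovery a
fair test. Anchor 12-mers are verified unique per genome (blocks resample
on collision).

Deliberately absent: non-uniform base composition and real repeat-family
structure, indel sequencing errors, PCR duplicates and stutter, adapter
contamination, coverage bias, and allele-length mutation between the
sampled chromosomes. Passing the end-to-end test therefore demonstrates
the pipeline's logic (orientation, clustering, allele calling, filter and
design geometry) under clean conditions, not robustness to every artefact
of a real sequencing run; the error-rate and mismatch-tolerance knobs
exist precisely because real data needs them.

Simulation sizes in the shipped tests (30 kb × 4 haplotypes, 10⁴ genotype
calls, 500-individual panels) were chosen as the smallest scales at which
the tested statistics have tight sampling distributions; all are
configurable upward.

## Degenerate inputs and tie-breaks

Empty reads scan to empty hit lists; all-missing loci raise explicit
no-data errors rather than returning NaN; an empty contaminant index is an
error distinct from "no match"; palindromic-flank orientation ties keep
the as-read orientation; consensus ties take the smaller base; cluster ids
are assigned after sorting clusters by (motif, consensus flanks), making
every output order-independent. All randomness flows from a single
configured seed.

## Known limitations

- Diploid genotypes are never called per individual from reads; the
  discovery side establishes polymorphism across chromosomes, and
  genotype tables are an input (from fragment analysis) on the evaluation
  side.
- The contaminant screen is ungapped; a diverged contaminant matching
  only with indels would be missed.
- Primer thermodynamics ignore hairpins, dimers and multiplex
  interactions — wet-lab optimization remains the arbiter.
- The repetitive-element rule is a proxy (low complexity + multi-copy
  anchors), not a curated repeat library.
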