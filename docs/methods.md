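# Methods

This note records the models, parameter defaults and design choices behind
`accelscan`, in the order the pipeline applies them. It states no empirical
result that the test suite does not itself compute.

## Substitution models and likelihoods

Two time-reversible nucleotide models are supported: JC69 and HKY85 (κ,
default 4.0; π either uniform, user-supplied, or estimated from the observed
base counts of the alignment). The generator `Q` is normalized so that the
expected equilibrium substitution rate is 1 per site per unit branch length;
branch lengths are therefore expected substitutions per site and rate scales
multiply them directly. `P(t) = exp(Qt)` is computed from the symmetric
eigendecomposition of `D_π^{1/2} Q D_π^{-1/2}` (exact for reversible models,
and cross-checked against a dense matrix exponential in the tests).

Column likelihoods use Felsenstein pruning with per-column rescaling and
site-pattern compression. Both `-` and `N` are treated as missing data
(partial-likelihood vector of ones), matching the convention of the standard
phylogenetic HMM toolkits; a species present in the tree but absent from an
alignment contributes missing data unless strict mode is requested.
Rate-variation-across-sites (Γ) and general GTR models are out of scope.

## Conserved-element detection

A two-state HMM emits alignment columns under two scalings of the same tree:
neutral (scale 1) and conserved (all branches × ρ). Parameters and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| ρ | conserved rate scale | 0.3 | typical conserved-element rate reduction; also the synthetic world's planted value |
| L_c | expected conserved length (bp) | 100 | exit probability μ = 1/L_c |
| L_n | expected neutral spacing (bp) | 1000 | entry probability ν = 1/L_n |

The chain starts from its stationary distribution; ν = 0 (infinite spacing)
degenerates to never entering the conserved state. Parameters are fixed per
run — there is no EM re-estimation or coverage autotuning — trading fidelity
to any particular tool's internal tuning for reproducibility. Elements are
maximal runs of the Viterbi conserved state; forward–backward posteriors are
computed alongside and the element score is the summed conserved-vs-neutral
log-odds. Columns where the reference row is gapped inherit the preceding
reference coordinate, so elements never have zero reference length.

**Merging.** Adjacent elements merge while
`gap / span(merged region) ≤ 0.1`, where the denominator is the span of the
would-be merged region *including* the gap — the ratio wording is ambiguous
and this reading is frozen here (the test oracle shares it). The scan runs
left to right to a fixed point; the tests prove it equivalent to a
best-ratio-pair-first strategy under this denominator. Elements shorter than
100 bp are retained through merging; the length filter applies afterwards,
at selection.

## Candidate selection

Selection keeps merged elements **strictly longer** than 100 bp that overlap
the peak union by ≥ 1 bp. After the focal-clade rows are restored
("unmasked"), per-species missing fractions are `(gaps + N) / columns` over
the candidate slice, each focal alignment species judged independently. The
filters drop a candidate when any restored focal row is **more than** 50%
missing, when **more than** 25% of its bases overlap a coding exon
(computed on reference coordinates, strand-ignored), or when fewer than one
focal taxon is present. The three predicates form a conjunction and are
order-independent; each drop is logged with its reason.

**Reciprocal best hit.** Genomes available only as contigs are added per
candidate: the candidate's ungapped reference sequence is locally aligned
(Smith–Waterman via Bio.Align: match +1, mismatch −2, gap open −5, extend
−2) against every contig of a species; the single best hit must pass an
e-value ≤ 0.01, computed from ungapped Karlin–Altschul statistics on the
local score (λ solved exactly for the score system; K fixed at 0.1 — an
acknowledged approximation to BLAST's gapped statistics that preserves the
threshold semantics and is configurable). The matched contig segment is then
aligned back to the reference genome — seeded on exact 12-mers so only the
best diagonal bands pay the dynamic-programming cost — and is accepted only
if the reverse best hit overlaps the original candidate interval by ≥ 1 bp
(the minimal faithful reading of "overlapped the original sequence").
Accepted segments are projected into the candidate's fixed column space via
the forward alignment; contig insertions relative to the reference are
dropped in that projection.

## The acceleration test

The null model holds every branch at its neutral length; conservation is
*not* re-fit per element (the design keeps a single fixed-ρ background), so
for genuinely conserved, unaccelerated elements the constrained fit pins at
the boundary and the test is conservative. The alternative frees a single
multiplier λ ≥ 1 on the focal clade's stem edge only — the "ancestral
lineage" — not on within-clade branches. λ is fit by bounded scalar search
on log λ over [1, 100] (tolerance 1e-6 on λ); a flat likelihood or any tie
with the boundary resolves to the bound, which guarantees `D ≥ 0`. P-values
come from the boundary mixture `½δ₀ + ½χ²₁`; a parametric bootstrap under
the fitted null is available (off by default) for very short alignments.
Benjamini–Hochberg is the default FDR procedure (Benjamini–Yekutieli behind
a flag); calls require `q < 0.05` strictly.

## Binding-site screen

PWMs carry a 0.01 pseudocount per column; the background defaults to uniform
and is overridable. Window log-odds scores (bits) are discretized to a 1e-3
bit grid and the exact null score distribution is the column-wise
convolution on that grid (widths ≤ 25). Both strands are scanned, windows
containing `N` are skipped, and hits are windows with BH-adjusted `q ≤ 0.01`
*within each sequence* (per-sequence correction; a genome-wide alternative
would be stricter and is deliberately not the default). Overlapping hits and
opposite-strand hits all count — trials are position-strand windows.

Gain/loss between a reconstructed ancestor and an extant ortholog uses a
conditional exact test: given `K = k_a + k_b` total hits, under the null
`k_a ~ Binomial(K, n_a/(n_a+n_b))`; the two-sided p-value sums all outcomes
no more probable than the observed one. This is a deliberate simplification
of the published correlated-binomial treatment of overlapping windows: hit
dependence within a sequence is ignored, which the type-I-error simulations
in the tests bound in aggregate but which can be anti-conservative for
self-overlapping motifs. The screen runs per element or pooled (counts and
trials summed over elements) with BH across motifs at `q < 0.05`.

## Ancestral reconstruction

Marginal (not joint) posteriors at the requested internal node, via the
standard inside–outside combination of pruning partials; the reported base
is the per-site MAP with ties broken by fixed order A < C < G < T, and sites
with no observed data anywhere below the node are reported as `N`.

## Annotation statistics

TSS distances use half-open interval-gap semantics from the element edges
(symmetric under coordinate reflection); a gene desert requires every TSS to
be strictly more than 500 kb away on both sides. The clustering statistic —
not specified by any upstream convention, so chosen here and labeled in the
output header — is the median same-chromosome nearest-neighbor distance
between element *midpoints*; the null resamples |called| candidates without
replacement from the candidate pool (count preserved, not length or
chromosome matched), and p-values use the add-one rule, so they are never
exactly 0 and are super-uniform by construction. Proximity enrichment builds
the (called × near) 2×2 table, "near" meaning within 1 Mb of any listed TSS,
with the Haldane–Anscombe 0.5 correction when a cell is empty, and a
one-sided resampling p for enrichment.

## Synthetic world

The generator's defaults are the conditions the pipeline is designed for: a
10-leaf tree (total length ≈ 2.6) whose 4-species focal clade has a stem of
0.12 substitutions/site; two focal species in the alignment and two present
only as contigs (so RBH integration is always exercised); a 200 kb reference
chromosome carrying 60 non-overlapping elements of 80–400 bp evolving at
ρ = 0.3, of which 10% carry λ = 10 on the stem — planted as stem scale ρ·λ
relative to neutral, i.e. acceleration relative to the element's own
background, mirroring the test's alternative (a switch allows whole-clade
scaling to probe misspecification). Whole-species dropout (rate 0.15 per
focal row per element) replaces rows with gaps so the missing-data filter
sees realistic structure; 80% of elements receive an overlapping peak, 8%
are mostly covered by a planted exon, and high-information 8-bp PWMs are
emitted alongside TSS/gene annotations. Truth tables carry each element's
rates, dropout, peak/exon status, realized stem substitution count and its
expected filter fate.

What the generator does **not** emulate: indel evolution (columns map 1:1 to
reference positions, so MAF blocks are artificially clean), base
composition heterogeneity, alignment error, chromatin-signal structure
beyond interval placement, and genome-scale repeat content. A green
end-to-end test therefore establishes the statistical machinery and the
plumbing, not robustness to alignment artifacts.

## Numerical details

- Pattern compression before pruning; per-column rescaling guards underflow.
- The 2-state HMM recursions run in scalar log-space (`log1p`-based
  log-add), exact to double precision and fast enough for 200 kb blocks.
- `q < threshold` is strict everywhere a call is made; filter boundaries
  follow the strict readings listed above (exactly 100 bp excluded, exactly
  25% exonic retained, exactly 50% missing retained).
- All randomness flows through `numpy.random.default_rng` seeded from the
  config; pipeline outputs contain no timestamps, so a rerun with identical
  inputs is byte-identical.

## Known limitations

- No Γ rate variation, GTR, or covarion models; no joint reconstruction.
- The RBH e-value is ungapped Karlin–Altschul on a gapped score, and the
  reverse search is seed-limited (an alignment with no exact 12-mer match
  reports no reverse hit).
- The count-divergence test ignores within-sequence hit correlation.
- Whether the reciprocal hit must be best genome-wide or merely best within
  the seeded bands is undetermined upstream; the seeded implementation
  approximates genome-wide best.
- Distance-based annotations use paper-scale defaults (1 Mb window, 500 kb
  radius) that are degenerate on the 200 kb toy chromosome; override them
  for synthetic-scale analyses.
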