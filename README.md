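# accelscan

Detection and characterization of **lineage-specific accelerated regions** in
conserved non-coding elements of a multiple genome alignment.

Deeply conserved non-coding elements that suddenly accumulate substitutions on
one branch of the species tree (the pattern behind human accelerated regions,
and the analogous bat accelerated regions) are prime candidates for
lineage-specific regulatory change. `accelscan` implements the full desk-scale
analysis for a comparative genomicist:

1. **Conserved-element detection** on an alignment with the focal clade
   removed, using a two-state phylogenetic HMM (neutral vs. conserved at rate
   scale ρ < 1), plus the iterative gap/length-ratio merging of fragmented
   elements.
2. **Candidate selection**: union of regulatory peak sets (e.g. ChIP-seq),
   intersection with merged elements > 100 bp, restoration of the focal-clade
   alignment rows, reciprocal-best-hit integration of genomes available only
   as contigs, and missing-data / coding-exon / clade-presence filters.
3. **Acceleration test**: a one-sided likelihood ratio test for an elevated
   substitution rate on the stem branch of the focal clade, with
   Benjamini–Hochberg FDR control over candidates.
4. **Characterization**: marginal ancestral-sequence reconstruction, a
   binding-site gain/loss screen (exact PWM score null distributions and a
   conditional-binomial count test), TSS-distance and gene-desert summaries,
   a clustering permutation test, and gene-proximity enrichment.
5. A **truth-labeled synthetic genome generator** that exercises every stage
   with no external data.

## The statistic at the core

Let `T` be a rooted tree with branch lengths `t` in expected substitutions
per site under a neutral model (JC69 or HKY85 with transition/transversion
ratio κ and equilibrium frequencies π; rate matrix `Q` normalized to one
expected substitution per site). For a candidate element alignment `X` and
the focal clade's stem edge `s`:

- null: all branches at their neutral lengths (stem scale λ = 1);
- alternative: the stem length is `λ·t_s` with λ ≥ 1 free (one-sided
  acceleration), all other branches unchanged;
- statistic: `D = 2(ln L(λ̂) − ln L(1))`, with likelihoods computed by
  Felsenstein pruning and gaps/`N` treated as missing data;
- reference distribution: the boundary mixture `½δ₀ + ½χ²₁` (the null pins λ
  on the edge of its range), so `p = ½·P(χ²₁ ≥ D)` for `D > 0` and `p = 1`
  at the boundary.

Elements with BH-adjusted `q < 0.05` (strict) are called accelerated.

## Worked example

Generate a synthetic bundle (10-species tree with a 4-species focal "bat"
clade, 200 kb chromosome, 60 planted conserved elements of which 10% are
accelerated at λ = 10 on the stem) and run the whole pipeline:

```bash
accelscan simulate --seed 7 --out demo/bundle
accelscan run-all --config demo/config.yaml --out demo/run
```

with `demo/config.yaml` pointing at the bundle files and naming the clade:

```yaml
maf: bundle/alignment.maf
newick: bundle/tree.nwk
peak_beds: [bundle/peaks_0.bed, bundle/peaks_1.bed]
exons_bed: bundle/exons.bed
tss_bed: bundle/tss.bed
genes_bed: bundle/genes.bed
contigs_fasta: bundle/contigs.fa
ref_genome_fasta: bundle/ref_genome.fa
pwms_jaspar: bundle/pwms.jaspar
focal_clade: [batA, batB, batC, batD]
aligned_focal: [batA, batB]
seed: 7
```

This prints `candidates: 28  accelerated: 1` and leaves per-stage files in
`demo/run/`. The stage log (`log.json`) shows the accounting — 62 detected
elements → 60 after merging → 45 peak-overlapping candidates → 28 after the
missing-data (14 dropped) and exon (3 dropped) filters — and
`acceleration.tsv` holds the per-candidate test:

```
id      lnl_null      lnl_alt       lambda_hat  stat      pvalue  qvalue  accelerated
cand0   -2097.244001  -2097.244001  1.0         0.0       1.0        1.0       False
...
cand16  -1005.065150  -991.812085   3.24019     26.506129 1.31e-07   3.68e-06  True
```

Unaccelerated candidates pin at the boundary (λ̂ = 1, D = 0, p = 1); the one
called region (`accelerated.bed`: `chrS 78644 78817 cand16`) overlaps a
planted accelerated element. `annotation_report.txt` summarizes TSS
distances, gene deserts, clustering and gene proximity for the called set;
`tfbs_screen.tsv` lists the per-motif ancestor-vs-reference gain/loss tests.

Note the toy chromosome is 200 kb, so paper-scale distance thresholds (1 Mb
proximity window, 500 kb desert radius) are intentionally degenerate in the
demo; pass a smaller `proximity_window` to make them informative at this
scale.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic bundle from the given seed, runs the full
pipeline end to end in a temporary directory, and writes the result JSON to
`--out`.

## Layout

- `src/accelscan/phylo.py` — trees, substitution models, pruning, simulation,
  branch-scale fitting, ancestral reconstruction
- `src/accelscan/conservation.py` — phylo-HMM element detection and merging
- `src/accelscan/candidates.py` — peak union, selection, unmasking, RBH, filters
- `src/accelscan/acceleration.py` — the LRT, BH correction, region calls
- `src/accelscan/tfbs.py` — PWM scanning and the count-divergence screen
- `src/accelscan/annotation.py` — distance, clustering and enrichment statistics
- `src/accelscan/synthetic.py` — truth-labeled bundle generator
- `src/accelscan/pipeline.py`, `src/accelscan/cli.py` — orchestration and CLI

See `docs/methods.md` for the model, parameter defaults and design choices.
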