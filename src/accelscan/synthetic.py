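"""Truth-labeled synthetic genome bundles.

Generates everything the pipeline consumes - a multi-species alignment with a
focal clade, planted conserved and accelerated elements, regulatory peaks,
exon and TSS annotations, contig-only extra genomes and a motif set - with a
per-element truth table for end-to-end evaluation.

The stated world: a 10-leaf tree whose focal clade has four species, two of
which appear in the alignment and two only as assembled contigs (so
reciprocal-best-hit integration is exercised); a 200 kb reference chromosome;
elements evolving at conserved rate scale rho = 0.3 with a 10 percent
accelerated subset whose focal-clade stem branch runs lambda = 10 times
faster than the element background; whole-species dropout per element so the
missing-data filter sees realistic structure.  No indel evolution is
simulated: alignment columns map one-to-one to reference positions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import MultipleAlignment, write_maf
from .intervals import GenomicInterval, write_bed
from .phylo import PhyloTree, SubstitutionModel, decode_codes, parse_newick, simulate_codes
from .tfbs import PWM, write_jaspar

DEFAULT_NEWICK = (
    "((((batA:0.07,batB:0.07)batAB:0.05,(batC:0.08,batD:0.08)batCD:0.04)"
    "batMRCA:0.12,(sp1:0.22,sp2:0.24)out1:0.08)clade1:0.1,"
    "((sp3:0.28,sp4:0.3)out2:0.12,(sp5:0.32,ref:0.2)out3:0.1)clade2:0.12)root;"
)


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults are the stated world described above."""

    seed: int
    newick: str = DEFAULT_NEWICK
    ref_species: str = "ref"
    focal_clade: tuple[str, ...] = ("batA", "batB", "batC", "batD")
    aligned_focal: tuple[str, ...] = ("batA", "batB")     # in the MAF
    contig_species: tuple[str, ...] = ("batC", "batD")    # contigs only
    chrom: str = "chrS"
    chrom_length: int = 200_000
    block_size: int = 10_000
    n_elements: int = 60
    element_length_range: tuple[int, int] = (80, 400)
    min_element_gap: int = 600
    rho: float = 0.3
    accel_fraction: float = 0.1
    lambdas: tuple[float, ...] = (10.0,)
    dropout_rate: float = 0.15           # whole focal row per element
    background_dropout: float = 0.05     # other non-reference rows
    peak_overlap_fraction: float = 0.8
    n_background_peaks: int = 15
    peak_length: int = 500
    n_peak_sets: int = 2
    exon_element_fraction: float = 0.08  # elements mostly covered by an exon
    n_background_exons: int = 8
    n_tss: int = 40
    n_genes: int = 10
    contig_fraction: float = 0.9
    contig_flank: int = 200
    n_decoy_contigs: int = 4
    n_pwms: int = 5
    pwm_width: int = 8
    pwm_dominant_prob: float = 0.85
    kappa: float = 4.0

    def __post_init__(self) -> None:
        for name in ("rho", "accel_fraction", "dropout_rate", "background_dropout",
                     "peak_overlap_fraction", "exon_element_fraction",
                     "contig_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "rho" and not 0 < v < 1):
                raise ValueError(f"{name}={v} outside its valid range")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticBundle:
    """In-memory bundle plus the truth table."""

    config: SyntheticConfig
    tree: PhyloTree
    model: SubstitutionModel
    blocks: list[MultipleAlignment]
    ref_genome: dict[str, str]
    peak_sets: list[list[GenomicInterval]]
    exons: list[GenomicInterval]
    tss: list[GenomicInterval]
    genes: list[GenomicInterval]
    contigs: dict[str, dict[str, str]]
    pwms: list[PWM]
    truth: pd.DataFrame

    @property
    def truth_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(r.chrom, r.start, r.end, name=r["name"])
                for _, r in self.truth.iterrows()]


def _place_elements(cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    lo, hi = cfg.element_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_elements)
    total = int(lengths.sum())
    n_gaps = cfg.n_elements + 1
    free = cfg.chrom_length - total - n_gaps * cfg.min_element_gap
    if free < 0:
        raise ValueError(
            f"infeasible packing: {cfg.n_elements} elements totalling {total} bp "
            f"plus gaps exceed chromosome length {cfg.chrom_length}"
        )
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
    spans: list[tuple[int, int]] = []
    pos = 0
    for i in range(cfg.n_elements):
        pos += cfg.min_element_gap + int(extra[i])
        spans.append((pos, pos + int(lengths[i])))
        pos += int(lengths[i])
    return spans


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Build the full bundle deterministically from config + seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = parse_newick(cfg.newick)
    model = SubstitutionModel.hky85(kappa=cfg.kappa)
    stem = tree.stem_edge(cfg.focal_clade)
    stem_parent = tree.names[int(tree.parent[tree.index(stem)])]

    spans = _place_elements(cfg, rng)
    n_acc = int(round(cfg.accel_fraction * cfg.n_elements))
    acc_idx = set(rng.choice(cfg.n_elements, size=n_acc, replace=False).tolist()) if n_acc else set()
    lam_of = {i: float(cfg.lambdas[k % len(cfg.lambdas)])
              for k, i in enumerate(sorted(acc_idx))}

    # --- simulate the chromosome segment by segment -----------------------
    species = tree.leaf_names
    chunks: dict[str, list[np.ndarray]] = {s: [] for s in species}
    stem_subs = {}
    cursor = 0
    for i, (start, end) in enumerate(spans):
        if start > cursor:
            seg = simulate_codes(tree, model, start - cursor, rng)
            for s in species:
                chunks[s].append(seg[s])
        lam = lam_of.get(i, 1.0)
        seg = simulate_codes(tree, model, end - start, rng,
                             scales={stem: lam}, rate_scale=cfg.rho)
        stem_subs[i] = int((seg[stem] != seg[stem_parent]).sum())
        for s in species:
            chunks[s].append(seg[s])
        cursor = end
    if cursor < cfg.chrom_length:
        seg = simulate_codes(tree, model, cfg.chrom_length - cursor, rng)
        for s in species:
            chunks[s].append(seg[s])
    seqs = {s: decode_codes(np.concatenate(chunks[s])) for s in species}
    ref_genome = {cfg.chrom: seqs[cfg.ref_species]}

    # --- per-element dropout (whole species replaced by gaps) -------------
    maf_species = [s for s in species if s not in set(cfg.contig_species)]
    rows = {s: list(seqs[s]) for s in maf_species}
    dropped: dict[int, list[str]] = {i: [] for i in range(cfg.n_elements)}
    for i, (start, end) in enumerate(spans):
        for s in maf_species:
            if s == cfg.ref_species:
                continue
            rate = cfg.dropout_rate if s in set(cfg.aligned_focal) else cfg.background_dropout
            if rng.random() < rate:
                rows[s][start:end] = ["-"] * (end - start)
                if s in set(cfg.aligned_focal):
                    dropped[i].append(s)
    maf_seqs = {s: "".join(v) for s, v in rows.items()}

    blocks = []
    for bstart in range(0, cfg.chrom_length, cfg.block_size):
        bend = min(bstart + cfg.block_size, cfg.chrom_length)
        blocks.append(MultipleAlignment(
            {s: maf_seqs[s][bstart:bend] for s in maf_species},
            cfg.ref_species, cfg.chrom, bstart))

    # --- peaks ------------------------------------------------------------
    peak_sets: list[list[GenomicInterval]] = [[] for _ in range(cfg.n_peak_sets)]
    peak_flag = {}
    pk = 0
    for i, (start, end) in enumerate(spans):
        hit = rng.random() < cfg.peak_overlap_fraction
        peak_flag[i] = hit
        if hit:
            center = (start + end) // 2 + int(rng.integers(-100, 101))
            half = cfg.peak_length // 2 + int(rng.integers(-50, 51))
            ps = max(0, center - half)
            pe = min(cfg.chrom_length, center + half)
            which = int(rng.integers(cfg.n_peak_sets))
            peak_sets[which].append(GenomicInterval(cfg.chrom, ps, pe, name=f"p{pk}"))
            pk += 1
    for _ in range(cfg.n_background_peaks):
        ps = int(rng.integers(0, cfg.chrom_length - cfg.peak_length))
        which = int(rng.integers(cfg.n_peak_sets))
        peak_sets[which].append(
            GenomicInterval(cfg.chrom, ps, ps + cfg.peak_length, name=f"p{pk}"))
        pk += 1
    peak_sets = [sorted(p, key=lambda iv: iv.start) for p in peak_sets]

    # --- exons ------------------------------------------------------------
    n_exonic = int(round(cfg.exon_element_fraction * cfg.n_elements))
    exonic = set(rng.choice(cfg.n_elements, size=n_exonic, replace=False).tolist()) if n_exonic else set()
    exons: list[GenomicInterval] = []
    exon_frac = {}
    for i, (start, end) in enumerate(spans):
        if i in exonic:
            width = max(1, int(0.4 * (end - start)))  # > 25 percent coverage
            exons.append(GenomicInterval(cfg.chrom, start, start + width, name=f"ex{len(exons)}"))
            exon_frac[i] = width / (end - start)
        else:
            exon_frac[i] = 0.0
    for _ in range(cfg.n_background_exons):
        es = int(rng.integers(0, cfg.chrom_length - 200))
        exons.append(GenomicInterval(cfg.chrom, es, es + 150, name=f"ex{len(exons)}"))
    exons = sorted(exons, key=lambda iv: iv.start)

    # --- TSS and gene list ------------------------------------------------
    tss_pos = sorted(rng.integers(0, cfg.chrom_length, size=cfg.n_tss).tolist())
    tss = [GenomicInterval(cfg.chrom, p, p + 1, name=f"tss{i}")
           for i, p in enumerate(tss_pos)]
    gene_idx = rng.choice(cfg.n_tss, size=min(cfg.n_genes, cfg.n_tss), replace=False)
    genes = [tss[i] for i in sorted(gene_idx.tolist())]

    # --- contigs for the contig-only species ------------------------------
    contigs: dict[str, dict[str, str]] = {s: {} for s in cfg.contig_species}
    contig_cover: dict[int, bool] = {}
    for i, (start, end) in enumerate(spans):
        cover = rng.random() < cfg.contig_fraction
        contig_cover[i] = cover
        if not cover:
            continue
        cs = max(0, start - cfg.contig_flank)
        ce = min(cfg.chrom_length, end + cfg.contig_flank)
        for s in cfg.contig_species:
            contigs[s][f"{s}_ctg{i}"] = seqs[s][cs:ce]
    for s in cfg.contig_species:
        for d in range(cfg.n_decoy_contigs):
            length = int(rng.integers(300, 800))
            contigs[s][f"{s}_decoy{d}"] = decode_codes(
                rng.integers(0, 4, size=length).astype(np.uint8))

    # --- motif set --------------------------------------------------------
    pwms = []
    for m in range(cfg.n_pwms):
        consensus = rng.integers(0, 4, size=cfg.pwm_width)
        mat = np.full((4, cfg.pwm_width), (1.0 - cfg.pwm_dominant_prob) / 3.0)
        for j, b in enumerate(consensus):
            mat[b, j] = cfg.pwm_dominant_prob
        pwms.append(PWM(f"M{m:02d}", mat))

    # --- truth table ------------------------------------------------------
    rows_t = []
    for i, (start, end) in enumerate(spans):
        length = end - start
        accelerated = i in acc_idx
        if length <= 100:
            fate = "short"
        elif not peak_flag[i]:
            fate = "no_peak"
        elif dropped[i]:
            fate = "missing"
        elif exon_frac[i] > 0.25:
            fate = "exon"
        else:
            fate = "candidate"
        rows_t.append({
            "name": f"el{i}",
            "chrom": cfg.chrom,
            "start": start,
            "end": end,
            "length": length,
            "rho": cfg.rho,
            "lam": lam_of.get(i, 1.0),
            "accelerated": accelerated,
            "peak_overlap": peak_flag[i],
            "dropped_species": ",".join(dropped[i]),
            "exon_fraction": round(exon_frac[i], 4),
            "contig_covered": contig_cover[i],
            "stem_substitutions": stem_subs[i],
            "expected_fate": fate,
        })
    truth = pd.DataFrame(rows_t)

    return SyntheticBundle(cfg, tree, model, blocks, ref_genome, peak_sets,
                           exons, tss, genes, contigs, pwms, truth)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle artifact in the formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    paths: dict[str, Path] = {}

    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(cfg.newick + "\n")

    paths["maf"] = out / "alignment.maf"
    src_sizes = {s: cfg.chrom_length for b in bundle.blocks for s in b.species}
    write_maf(bundle.blocks, paths["maf"], src_sizes)

    for k, peaks in enumerate(bundle.peak_sets):
        p = out / f"peaks_{k}.bed"
        write_bed(peaks, p)
        paths[f"peaks_{k}"] = p
    write_bed(bundle.exons, out / "exons.bed")
    paths["exons"] = out / "exons.bed"
    write_bed(bundle.tss, out / "tss.bed")
    paths["tss"] = out / "tss.bed"
    write_bed(bundle.genes, out / "genes.bed")
    paths["genes"] = out / "genes.bed"

    paths["ref_genome"] = out / "ref_genome.fa"
    with open(paths["ref_genome"], "w") as fh:
        for chrom, seq in bundle.ref_genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    paths["contigs"] = out / "contigs.fa"
    with open(paths["contigs"], "w") as fh:
        for sp in sorted(bundle.contigs):
            for name in sorted(bundle.contigs[sp]):
                fh.write(f">{name} species={sp}\n")
                seq = bundle.contigs[sp][name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    paths["pwms"] = out / "pwms.jaspar"
    write_jaspar(bundle.pwms, paths["pwms"])

    paths["truth"] = out / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)

    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return paths


def read_contigs_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a contig FASTA whose headers carry ``species=<name>``; contigs
    without the tag fall under species inferred from the id prefix."""
    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = None
        for tok in rec.description.split():
            if tok.startswith("species="):
                sp = tok.split("=", 1)[1]
        if sp is None:
            sp = rec.id.split("_", 1)[0]
        out.setdefault(sp, {})[rec.id] = str(rec.seq).upper()
    return out


def evaluate_calls(calls: Sequence[GenomicInterval],
                   truth: Sequence[GenomicInterval],
                   min_reciprocal_overlap: float = 0.5) -> dict[str, float]:
    """Sensitivity, false-discovery proportion and base-level Jaccard of a
    call set against planted truth intervals.

    A call matches a truth interval when their overlap covers at least
    `min_reciprocal_overlap` of BOTH intervals.
    """
    def matches(a: GenomicInterval, b: GenomicInterval) -> bool:
        ov = a.overlap_bases(b)
        return (ov >= min_reciprocal_overlap * len(a)
                and ov >= min_reciprocal_overlap * len(b))

    matched_truth = sum(1 for t in truth if any(matches(c, t) for c in calls))
    matched_calls = sum(1 for c in calls if any(matches(c, t) for t in truth))
    sensitivity = matched_truth / len(truth) if truth else 1.0
    fdp = (len(calls) - matched_calls) / len(calls) if calls else 0.0

    from .intervals import covered_bases
    union = covered_bases(list(calls) + list(truth))
    inter = covered_bases(list(calls)) + covered_bases(list(truth)) - union
    jaccard = inter / union if union else 1.0
    return {"sensitivity": sensitivity, "fdp": fdp, "jaccard": jaccard}
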