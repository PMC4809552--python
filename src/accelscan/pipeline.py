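"""End-to-end orchestration: mask -> detect -> merge -> select -> unmask ->
RBH -> filter -> test -> FDR -> call -> reconstruct -> TFBS screen -> annotate.

Every stage writes a TSV/BED intermediate into the run directory, record
counts and drop reasons go to a machine-readable ``log.json`` (no timestamps,
so reruns with identical inputs are byte-identical), and records keep stable
ids across stage files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import acceleration as accel
from . import annotation as annot
from . import candidates as cand
from . import conservation as cons
from .alignment import MultipleAlignment, read_maf, slice_blocks
from .intervals import GenomicInterval, read_bed, write_bed
from .phylo import (
    PhyloTree,
    SubstitutionModel,
    estimate_base_frequencies,
    parse_newick,
    reconstruct_ancestor,
)
from .synthetic import read_contigs_fasta
from .tfbs import divergence_screen, read_jaspar


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """File paths, focal clade and every stage threshold (defaults as in the
    underlying study design: merge ratio 0.1, minimum length 100 bp, maximum
    missing fraction 0.5, maximum exon fraction 0.25, e-value 0.01,
    acceleration FDR 0.05, hit FDR 0.01, screen FDR 0.05, proximity window
    1 Mb, gene-desert radius 500 kb)."""

    maf: str
    newick: str
    peak_beds: list[str]
    exons_bed: str
    tss_bed: str
    focal_clade: list[str]
    aligned_focal: list[str]          # focal rows present in the MAF (masked/unmasked)
    genes_bed: str | None = None
    contigs_fasta: str | None = None
    ref_genome_fasta: str | None = None
    pwms_jaspar: str | None = None

    model_family: str = "HKY85"
    kappa: float = 4.0
    pi_from_data: bool = True

    rho: float = 0.3
    expected_conserved_length: float = 100.0
    expected_neutral_length: float = 1000.0

    merge_ratio: float = 0.1
    min_length: int = 100
    max_missing: float = 0.5
    max_exon_frac: float = 0.25
    min_focal: int = 1
    evalue: float = 0.01
    accel_fdr: float = 0.05
    fdr_method: str = "fdr_bh"
    hit_fdr: float = 0.01
    screen_fdr: float = 0.05
    proximity_window: int = 1_000_000
    desert_radius: int = 500_000
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def resolve_paths(self, base: Path) -> "PipelineConfig":
        def r(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p
        self.maf = r(self.maf)
        self.newick = r(self.newick)
        self.peak_beds = [r(p) for p in self.peak_beds]
        self.exons_bed = r(self.exons_bed)
        self.tss_bed = r(self.tss_bed)
        for attr in ("genes_bed", "contigs_fasta", "ref_genome_fasta", "pwms_jaspar"):
            setattr(self, attr, r(getattr(self, attr)))
        return self


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the pipeline; returns the summary dict also written to log.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "config": asdict(config)}

    def stage(name: str, **counts):
        log["stages"][name] = counts

    # ---- load ------------------------------------------------------------
    try:
        blocks = read_maf(config.maf)
        tree = parse_newick(Path(config.newick).read_text())
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    if not blocks:
        raise StageError("load", "no alignment blocks")
    if config.pi_from_data:
        pi = estimate_base_frequencies(s for b in blocks for s in b.seqs.values())
    else:
        pi = None
    model = (SubstitutionModel.jc69() if config.model_family.upper() == "JC69"
             else SubstitutionModel.hky85(kappa=config.kappa, pi=pi))
    stage("load", blocks=len(blocks), species=len(blocks[0].species))

    # ---- mask + detect ---------------------------------------------------
    params = cons.PhyloHmmParams(config.rho, config.expected_conserved_length,
                                 config.expected_neutral_length)
    detected: list[cons.ConservedElement] = []
    for b in blocks:
        masked = cons.mask_species(b, config.aligned_focal)
        for el in cons.detect_conserved(masked, tree, model, params):
            el.interval = GenomicInterval(el.interval.chrom, el.interval.start,
                                          el.interval.end, name=f"ce{len(detected)}")
            detected.append(el)
    write_bed(cons.elements_to_bed(detected), out / "conserved.bed")
    stage("detect", elements=len(detected))

    # ---- merge -----------------------------------------------------------
    merged = cons.merge_elements(detected, config.merge_ratio)
    merged_iv = [GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                                 name=f"me{i}", score=e.score)
                 for i, e in enumerate(merged)]
    write_bed(merged_iv, out / "merged.bed")
    stage("merge", elements=len(merged))

    # ---- peaks + select --------------------------------------------------
    try:
        peak_sets = [read_bed(p) for p in config.peak_beds]
    except ValueError as exc:
        raise StageError("peaks", str(exc)) from exc
    peaks = cand.union_peaks(peak_sets)
    write_bed(peaks, out / "peaks_union.bed")
    candidates = cand.select_candidates(merged_iv, peaks, config.min_length)
    stage("select", peaks=len(peaks), candidates=len(candidates))

    # ---- unmask ----------------------------------------------------------
    for c in candidates:
        cand.unmask_species(c, blocks, config.aligned_focal)
    stage("unmask", candidates=len(candidates))

    # ---- RBH -------------------------------------------------------------
    rbh_log = []
    if config.contigs_fasta and config.ref_genome_fasta:
        contig_db = read_contigs_fasta(config.contigs_fasta)
        genome_index = cand.GenomeSeedIndex(_read_fasta(config.ref_genome_fasta))
        for c in candidates:
            _, decisions = cand.rbh_integrate(c, contig_db, genome_index,
                                              evalue_max=config.evalue)
            for d in decisions:
                rbh_log.append({"candidate": c.id, "species": d.species,
                                "accepted": d.accepted, "reason": d.reason,
                                "contig": d.contig})
    stage("rbh", attempts=len(rbh_log),
          accepted=sum(1 for d in rbh_log if d["accepted"]))

    # ---- filter ----------------------------------------------------------
    exons = read_bed(config.exons_bed)
    kept = cand.apply_filters(candidates, exons, config.focal_clade,
                              unmasked_species=config.aligned_focal,
                              max_missing=config.max_missing,
                              max_exon_frac=config.max_exon_frac,
                              min_focal=config.min_focal)
    cand_rows = []
    for c in candidates:
        cand_rows.append({
            "id": c.id, "chrom": c.interval.chrom, "start": c.interval.start,
            "end": c.interval.end, "peaks": ",".join(c.peak_ids),
            "exon_fraction": round(c.exon_fraction, 4),
            "focal_taxa": c.focal_taxa_count,
            **{f"missing_{sp}": round(c.missing_fraction.get(sp, 1.0), 4)
               for sp in config.aligned_focal},
            "drop_reason": c.drop_reason or "",
        })
    pd.DataFrame(cand_rows).to_csv(out / "candidates.tsv", sep="\t", index=False)
    drop_counts: dict[str, int] = {}
    for c in candidates:
        if c.drop_reason:
            key = c.drop_reason.split("=")[0].split("[")[0]
            drop_counts[key] = drop_counts.get(key, 0) + 1
    stage("filter", kept=len(kept), dropped=len(candidates) - len(kept),
          drop_reasons=drop_counts)

    # ---- acceleration test + FDR + call ---------------------------------
    results = []
    for c in kept:
        try:
            res = accel.acceleration_test(c.alignment, tree, model,
                                          config.focal_clade, candidate_id=c.id)
        except Exception as exc:
            raise StageError("test", f"candidate {c.id}: {exc}") from exc
        results.append(res)
    accel.call_accelerated(results, config.accel_fdr, method=config.fdr_method)
    res_df = pd.DataFrame([{
        "id": r.candidate_id, "lnl_null": round(r.lnl_null, 6),
        "lnl_alt": round(r.lnl_alt, 6), "lambda_hat": round(r.lambda_hat, 6),
        "stat": round(r.stat, 6), "pvalue": r.pvalue, "qvalue": r.qvalue,
        "accelerated": r.is_accelerated} for r in results])
    res_df.to_csv(out / "acceleration.tsv", sep="\t", index=False)
    by_id = {c.id: c for c in kept}
    bars = [by_id[r.candidate_id].interval for r in results if r.is_accelerated]
    bars = [GenomicInterval(b.chrom, b.start, b.end, name=b.name,
                            score=next(r.stat for r in results
                                       if r.candidate_id == b.name))
            for b in bars]
    write_bed(bars, out / "accelerated.bed")
    stage("call", tested=len(results), accelerated=len(bars))

    # ---- ancestral reconstruction + TFBS screen -------------------------
    screen_df = pd.DataFrame()
    if config.pwms_jaspar and bars:
        pwms = read_jaspar(config.pwms_jaspar)
        anc_node = tree.mrca(config.focal_clade)
        pairs = []
        for b in bars:
            c = by_id[b.name]
            codes = {s: v for s, v in c.alignment.codes().items()
                     if s in set(tree.leaf_names)}
            anc_seq, _ = reconstruct_ancestor(tree, model, codes, anc_node)
            ref_row = c.alignment.seqs[c.alignment.ref]
            keep = [i for i, ch in enumerate(ref_row) if ch != "-"]
            pairs.append((b.name,
                          "".join(anc_seq[i] for i in keep),
                          "".join(ref_row[i] for i in keep)))
        screen_df = divergence_screen(pairs, pwms, pooled=True,
                                      hit_fdr=config.hit_fdr,
                                      screen_fdr=config.screen_fdr)
    screen_df.to_csv(out / "tfbs_screen.tsv", sep="\t", index=False)
    n_gain = int((screen_df.get("significant", pd.Series(dtype=bool))
                  & (screen_df.get("direction", pd.Series(dtype=str)) == "gain")).sum()) \
        if not screen_df.empty else 0
    n_loss = int((screen_df.get("significant", pd.Series(dtype=bool))
                  & (screen_df.get("direction", pd.Series(dtype=str)) == "loss")).sum()) \
        if not screen_df.empty else 0
    stage("tfbs", motifs=0 if screen_df.empty else int(screen_df.shape[0]),
          significant_gain=n_gain, significant_loss=n_loss)

    # ---- annotation ------------------------------------------------------
    tss = read_bed(config.tss_bed)
    report = annot.summary_report(bars, tss, config.desert_radius)
    candidate_iv = [c.interval for c in kept]
    if len(bars) >= 2:
        p_clust, stat_clust = annot.clustering_permutation_test(
            bars, candidate_iv, n_perm=config.n_perm, seed=config.seed)
        report["clustering_p"] = p_clust
        report["clustering_median_nn_bp"] = stat_clust
    if config.genes_bed and bars:
        genes = read_bed(config.genes_bed)
        enr = annot.proximity_enrichment(bars, candidate_iv, genes,
                                         window=config.proximity_window,
                                         n_perm=config.n_perm, seed=config.seed)
        report["proximity_odds_ratio"] = enr.odds_ratio
        report["proximity_p"] = enr.pvalue
        report["proximity_table"] = [enr.near_bar, enr.far_bar,
                                     enr.near_other, enr.far_other]
    with open(out / "annotation_report.txt", "w") as fh:
        fh.write("# accelerated-region annotation summary\n")
        fh.write("# clustering statistic: median same-chromosome nearest-neighbor "
                 "midpoint distance; resampling: candidate draws without replacement\n")
        for k in sorted(report):
            fh.write(f"{k}\t{report[k]}\n")
    stage("annotate", **{k: v for k, v in report.items()
                         if isinstance(v, (int, float)) and np.isfinite(v)})

    log["summary"] = {
        "candidates": len(kept),
        "accelerated": len(bars),
        "mean_accelerated_length": (float(np.mean([len(b) for b in bars]))
                                    if bars else 0.0),
    }
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return log
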