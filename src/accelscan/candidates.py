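"""Candidate enhancer construction.

Builds the tested element set from merged conserved elements and regulatory
peaks: peak union, length/overlap selection, restoring (unmasking) the
focal-clade rows of the alignment, reciprocal-best-hit integration of
additional genomes available only as contigs, and the missing-data / coding
/ clade-presence filters.

The local alignments behind the RBH step use Smith-Waterman scoring
(match +1, mismatch -2, gap open -5, extend -2) via Bio.Align, with e-values
from ungapped Karlin-Altschul statistics applied to the local score - an
approximation to BLAST's statistics with the same threshold semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .alignment import MultipleAlignment, slice_blocks
from .intervals import (
    GenomicInterval,
    merge_overlapping,
    overlap_fraction,
    sort_intervals,
)


@dataclass
class CandidateEnhancer:
    """A candidate element and everything the filters need to judge it."""

    interval: GenomicInterval
    peak_ids: list[str] = field(default_factory=list)
    alignment: MultipleAlignment | None = None
    missing_fraction: dict[str, float] = field(default_factory=dict)
    exon_fraction: float = 0.0
    focal_present: list[str] = field(default_factory=list)
    drop_reason: str | None = None

    @property
    def id(self) -> str:
        return self.interval.name

    @property
    def focal_taxa_count(self) -> int:
        return len(self.focal_present)


def union_peaks(peak_sets: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Disjoint sorted union of several peak interval sets."""
    pooled = [iv for peaks in peak_sets for iv in peaks]
    merged = merge_overlapping(pooled)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak{i}")
        for i, iv in enumerate(merged)
    ]


def select_candidates(merged_elements: Sequence[GenomicInterval],
                      peaks: Sequence[GenomicInterval],
                      min_length: int = 100) -> list[CandidateEnhancer]:
    """Keep elements strictly longer than `min_length` that overlap >= 1 peak
    by >= 1 bp; contributing peak ids are recorded."""
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in sort_intervals(peaks):
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    out: list[CandidateEnhancer] = []
    for i, el in enumerate(sort_intervals(merged_elements)):
        if len(el) <= min_length:
            continue
        hits = [p.name for p in peaks_by_chrom.get(el.chrom, ()) if el.overlaps(p)]
        if not hits:
            continue
        iv = GenomicInterval(el.chrom, el.start, el.end,
                             name=f"cand{len(out)}", score=el.score)
        out.append(CandidateEnhancer(interval=iv, peak_ids=hits))
    return out


def unmask_species(candidate: CandidateEnhancer,
                   full_blocks: Sequence[MultipleAlignment],
                   species: Sequence[str]) -> CandidateEnhancer:
    """Attach the candidate's alignment slice from the unmasked blocks and
    compute per-species missing fractions for the restored rows."""
    iv = candidate.interval
    aln = slice_blocks(full_blocks, iv.chrom, iv.start, iv.end)
    candidate.alignment = aln
    for sp in species:
        candidate.missing_fraction[sp] = aln.missing_fraction(sp)
    return candidate


def compute_exon_fraction(candidate: CandidateEnhancer,
                          exons: Sequence[GenomicInterval]) -> CandidateEnhancer:
    candidate.exon_fraction = overlap_fraction(candidate.interval, exons)
    return candidate


def update_focal_presence(candidate: CandidateEnhancer,
                          focal_species: Sequence[str]) -> CandidateEnhancer:
    """Focal taxa counted present when their row has >= 1 non-missing base."""
    aln = candidate.alignment
    present = []
    if aln is not None:
        for sp in focal_species:
            if sp in aln.seqs and aln.missing_fraction(sp) < 1.0:
                present.append(sp)
    candidate.focal_present = present
    return candidate


def apply_filters(candidates: Sequence[CandidateEnhancer],
                  exons: Sequence[GenomicInterval],
                  focal_species: Sequence[str],
                  unmasked_species: Sequence[str] | None = None,
                  max_missing: float = 0.5,
                  max_exon_frac: float = 0.25,
                  min_focal: int = 1) -> list[CandidateEnhancer]:
    """Drop candidates violating any of the three predicates.

    * more than `max_missing` missing sequence in any of the unmasked
      focal rows (strictly greater drops; exactly the threshold is retained);
    * more than `max_exon_frac` of bases overlapping a coding exon
      (strictly greater drops);
    * fewer than `min_focal` focal taxa present.

    Survivors are returned; every input candidate gets a `drop_reason`
    (None for survivors). The conjunction is order-independent.
    """
    unmasked_species = list(unmasked_species if unmasked_species is not None
                            else focal_species)
    kept: list[CandidateEnhancer] = []
    for cand in candidates:
        compute_exon_fraction(cand, exons)
        update_focal_presence(cand, focal_species)
        reasons = []
        for sp in unmasked_species:
            frac = cand.missing_fraction.get(sp, 1.0)
            if frac > max_missing:
                reasons.append(f"missing[{sp}]={frac:.3f}")
        if cand.exon_fraction > max_exon_frac:
            reasons.append(f"exon={cand.exon_fraction:.3f}")
        if cand.focal_taxa_count < min_focal:
            reasons.append(f"focal_taxa={cand.focal_taxa_count}")
        cand.drop_reason = "; ".join(reasons) if reasons else None
        if cand.drop_reason is None:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------


def _sw_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def karlin_altschul_lambda(match: float = 1.0, mismatch: float = -2.0,
                           gc: float = 0.5) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1 for the ungapped
    match/mismatch score system."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_match = float((p * p).sum())

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def sw_evalue(score: float, query_len: int, db_len: int,
              lam: float | None = None, K: float = 0.1) -> float:
    """Ungapped Karlin-Altschul e-value for a local alignment score."""
    if lam is None:
        lam = karlin_altschul_lambda()
    return float(K * query_len * db_len * math.exp(-lam * score))


class GenomeSeedIndex:
    """Exact k-mer index of a genome for seeded local alignment.

    The reverse step of the RBH procedure needs the best local alignment of a
    short segment against a whole reference genome; full dynamic programming
    against every chromosome is wasteful, so hits are seeded on exact k-mer
    matches (as BLAST does) and Smith-Waterman runs only inside the seeded
    window.  Segments with no exact k-mer match report no alignment.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 12,
                 max_occurrences: int = 100):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                hits = self.index.setdefault(kmer, [])
                if len(hits) <= max_occurrences:
                    hits.append((chrom, i))
        # drop over-represented seeds entirely (repeat-like)
        self.index = {km: h for km, h in self.index.items()
                      if len(h) <= max_occurrences}

    def best_local(self, aligner: Align.PairwiseAligner, query: str,
                   pad: int = 200):
        """(chrom, alignment, window_offset) of the best seeded local hit."""
        k = self.k
        votes: dict[tuple[str, int], int] = {}
        for qo in range(0, len(query) - k + 1):
            for chrom, p in self.index.get(query[qo:qo + k], ()):
                diag = (p - qo) // 100
                for d in (diag, diag + 1):
                    key = (chrom, d)
                    votes[key] = votes.get(key, 0) + 1
        if not votes:
            return None
        best = None
        # examine the few best-voted diagonal bands
        for (chrom, d), _ in sorted(votes.items(), key=lambda kv: -kv[1])[:5]:
            seq = self.genome[chrom]
            w0 = max(0, d * 100 - pad)
            w1 = min(len(seq), d * 100 + 100 + len(query) + pad)
            alns = aligner.align(query, seq[w0:w1])
            if len(alns) == 0:
                continue
            top = alns[0]
            if best is None or top.score > best[1].score:
                best = (chrom, top, w0)
        return best


@dataclass
class RbhDecision:
    """Record of one reciprocal-best-hit attempt (for the stage log)."""

    species: str
    accepted: bool
    reason: str
    contig: str | None = None
    forward_score: float = 0.0
    forward_evalue: float = math.inf
    reverse_interval: GenomicInterval | None = None


def _best_local(aligner: Align.PairwiseAligner, query: str,
                targets: Mapping[str, str]):
    """Highest-scoring local alignment of query against a set of sequences."""
    best = None
    for name in sorted(targets):
        seq = targets[name]
        if not seq:
            continue
        aln = aligner.align(query, seq)
        if len(aln) == 0:
            continue
        top = aln[0]
        if best is None or top.score > best[1].score:
            best = (name, top)
    return best


def rbh_integrate(candidate: CandidateEnhancer,
                  contig_db: Mapping[str, Mapping[str, str]],
                  ref_genome: "Mapping[str, str] | GenomeSeedIndex",
                  evalue_max: float = 0.01,
                  K: float = 0.1) -> tuple[CandidateEnhancer, list[RbhDecision]]:
    """Add contig-only genomes to a candidate's alignment by reciprocal best hit.

    For each species in `contig_db` (species -> {contig id -> sequence}): the
    candidate's ungapped reference sequence is locally aligned against every
    contig; the single best hit must pass e <= `evalue_max`, and the matched
    contig segment's best local alignment back to the reference genome must
    overlap the candidate interval by >= 1 bp.  Accepted segments are added as
    a new alignment row, projected onto the candidate's columns via the
    forward alignment (contig insertions relative to the reference are
    dropped).  Every decision is returned for the stage log.
    """
    aln = candidate.alignment
    if aln is None:
        raise ValueError("candidate has no alignment slice; run unmask first")
    decisions: list[RbhDecision] = []
    ref_row = aln.seqs[aln.ref]
    query = ref_row.replace("-", "")
    aligner = _sw_aligner()
    lam = karlin_altschul_lambda()
    genome_index = (ref_genome if isinstance(ref_genome, GenomeSeedIndex)
                    else GenomeSeedIndex(ref_genome))

    for species in sorted(contig_db):
        contigs = contig_db[species]
        if not contigs:
            decisions.append(RbhDecision(species, False, "empty contig database"))
            continue
        fwd = _best_local(aligner, query, contigs)
        if fwd is None:
            decisions.append(RbhDecision(species, False, "no forward alignment"))
            continue
        contig_name, top = fwd
        db_len = sum(len(s) for s in contigs.values())
        ev = sw_evalue(top.score, len(query), db_len, lam=lam, K=K)
        if ev > evalue_max:
            decisions.append(RbhDecision(species, False,
                                         f"forward e-value {ev:.3g} > {evalue_max}",
                                         contig=contig_name, forward_score=top.score,
                                         forward_evalue=ev))
            continue
        # reverse: matched contig segment vs the reference genome
        q_blocks, t_blocks = top.aligned
        seg_start, seg_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
        segment = contigs[contig_name][seg_start:seg_end]
        rev = genome_index.best_local(aligner, segment)
        if rev is None:
            decisions.append(RbhDecision(species, False, "no reverse alignment",
                                         contig=contig_name, forward_score=top.score,
                                         forward_evalue=ev))
            continue
        rev_chrom, rev_top, rev_off = rev
        rb = rev_top.aligned[1]
        rev_iv = GenomicInterval(rev_chrom, rev_off + int(rb[0][0]),
                                 rev_off + int(rb[-1][1]))
        if not rev_iv.overlaps(candidate.interval):
            decisions.append(RbhDecision(species, False,
                                         "reverse best hit maps elsewhere",
                                         contig=contig_name, forward_score=top.score,
                                         forward_evalue=ev, reverse_interval=rev_iv))
            continue
        row = _project_contig_row(aln, query, contigs[contig_name], top)
        candidate.alignment = aln = aln.with_row(species, row)
        candidate.missing_fraction[species] = aln.missing_fraction(species)
        decisions.append(RbhDecision(species, True, "reciprocal best hit",
                                     contig=contig_name, forward_score=top.score,
                                     forward_evalue=ev, reverse_interval=rev_iv))
    return candidate, decisions


def _project_contig_row(aln: MultipleAlignment, query: str, contig: str,
                        top) -> str:
    """Place contig bases into the candidate's column space using the forward
    local alignment of the ungapped reference sequence to the contig."""
    per_query = ["-"] * len(query)
    q_blocks, t_blocks = top.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for k in range(qe - qs):
            per_query[qs + k] = contig[ts + k]
    # expand to gapped columns of the slice
    row = []
    qi = 0
    for c in aln.seqs[aln.ref]:
        if c == "-":
            row.append("-")
        else:
            row.append(per_query[qi])
            qi += 1
    return "".join(row)
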