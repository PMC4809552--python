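"""Candidate construction: peak union, selection, unmasking, filters, RBH."""

import numpy as np
import pytest

from accelscan.alignment import MultipleAlignment
from accelscan.candidates import (
    CandidateEnhancer,
    GenomeSeedIndex,
    _sw_aligner,
    apply_filters,
    karlin_altschul_lambda,
    rbh_integrate,
    select_candidates,
    sw_evalue,
    union_peaks,
    unmask_species,
)
from accelscan.intervals import GenomicInterval


def _iv(start, end, chrom="chr1", name=""):
    return GenomicInterval(chrom, start, end, name=name)


class TestUnionPeaks:
    def test_overlapping_pair(self):
        out = union_peaks([[_iv(0, 100)], [_iv(50, 150)]])
        assert [(p.start, p.end) for p in out] == [(0, 150)]

    def test_disjoint_inputs_unchanged_count(self):
        out = union_peaks([[_iv(0, 10), _iv(50, 60)], [_iv(100, 120)]])
        assert len(out) == 3

    def test_covered_bases_match_bitmap_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sets = []
            bitmap = np.zeros(10_000, dtype=bool)
            for _ in range(3):
                peaks = []
                for _ in range(int(rng.integers(1, 15))):
                    s = int(rng.integers(0, 9_500))
                    e = s + int(rng.integers(1, 500))
                    peaks.append(_iv(s, min(e, 10_000)))
                    bitmap[s:min(e, 10_000)] = True
                sets.append(peaks)
            out = union_peaks(sets)
            assert sum(len(p) for p in out) == int(bitmap.sum())
            for a, b in zip(out, out[1:]):  # disjoint and sorted
                assert a.end < b.start or a.chrom != b.chrom


class TestSelectCandidates:
    PEAKS = [_iv(500, 700, name="p0")]

    def test_exactly_min_length_excluded(self):
        els = [_iv(400, 500, name="e")]  # length 100, not > 100
        assert select_candidates(els, [_iv(400, 600)]) == []

    def test_one_bp_overlap_included(self):
        els = [_iv(350, 501, name="e")]  # length 151, overlaps peak by 1 bp
        out = select_candidates(els, self.PEAKS)
        assert len(out) == 1
        assert out[0].peak_ids == ["p0"]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            els = []
            pos = 0
            for i in range(int(rng.integers(1, 20))):
                pos += int(rng.integers(1, 200))
                w = int(rng.integers(50, 300))
                els.append(_iv(pos, pos + w, name=f"e{i}"))
                pos += w
            peaks = [_iv(int(s), int(s) + 150, name=f"p{k}")
                     for k, s in enumerate(rng.integers(0, 4000, size=5))]
            got = {(c.interval.start, c.interval.end)
                   for c in select_candidates(els, peaks)}
            want = {(e.start, e.end) for e in els
                    if len(e) > 100 and any(e.overlaps(p) for p in peaks)}
            assert got == want

    def test_survivors_are_subset_and_overlap_a_peak(self):
        els = [_iv(0, 400, name="a"), _iv(600, 650, name="b"),
               _iv(800, 1000, name="c")]
        for c in select_candidates(els, self.PEAKS):
            assert any(c.interval.overlaps(p) for p in self.PEAKS)
            assert any(c.interval.start == e.start and c.interval.end == e.end
                       for e in els)


def _blocks(width=100, start=0):
    """Single block: ref + two focal rows with controlled missingness."""
    ref = "A" * width
    bat1 = "A" * width
    bat2 = "-" * 30 + "A" * (width - 30)
    other = "C" * width
    return [MultipleAlignment({"ref": ref, "batA": bat1, "batB": bat2,
                               "sp1": other}, "ref", "chr1", start)]


class TestUnmaskAndFilters:
    def test_missing_fractions(self):
        c = CandidateEnhancer(interval=_iv(0, 100, name="c0"))
        unmask_species(c, _blocks(), ["batA", "batB"])
        assert c.missing_fraction["batA"] == pytest.approx(0.0)
        assert c.missing_fraction["batB"] == pytest.approx(0.30)

    def test_absent_species_fraction_one(self):
        c = CandidateEnhancer(interval=_iv(0, 100, name="c0"))
        unmask_species(c, _blocks(), ["batA", "batZ"])
        assert c.missing_fraction["batZ"] == 1.0

    @pytest.mark.parametrize("missing,kept", [(0.60, False), (0.50, True),
                                              (0.30, True)])
    def test_missing_boundary(self, missing, kept):
        c = CandidateEnhancer(interval=_iv(0, 100, name="c0"),
                              alignment=_blocks()[0],
                              missing_fraction={"batA": missing, "batB": 0.0})
        out = apply_filters([c], [], ["batA", "batB"])
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("exon_end,kept", [(30, False), (25, True)])
    def test_exon_boundary(self, exon_end, kept):
        """Strictly more than 25% exonic drops; exactly 25% is retained."""
        c = CandidateEnhancer(interval=_iv(0, 100, name="c0"),
                              alignment=_blocks()[0],
                              missing_fraction={"batA": 0.0, "batB": 0.0})
        out = apply_filters([c], [_iv(0, exon_end)], ["batA", "batB"])
        assert (len(out) == 1) is kept

    def test_no_focal_taxa_dropped(self):
        block = MultipleAlignment({"ref": "A" * 50, "sp1": "C" * 50},
                                  "ref", "chr1", 0)
        c = CandidateEnhancer(interval=_iv(0, 50, name="c0"), alignment=block,
                              missing_fraction={"batA": 0.0, "batB": 0.0})
        out = apply_filters([c], [], ["batA", "batB", "batC", "batD"])
        assert out == []
        assert "focal_taxa" in c.drop_reason

    def test_survivors_satisfy_all_predicates(self):
        rng = np.random.default_rng(14)
        cands = []
        for i in range(30):
            width = 100
            nmiss = int(rng.integers(0, width))
            seq = "-" * nmiss + "A" * (width - nmiss)
            block = MultipleAlignment({"ref": "A" * width, "batA": seq,
                                       "batB": "A" * width}, "ref", "chr1", 0)
            c = CandidateEnhancer(interval=_iv(0, width, name=f"c{i}"),
                                  alignment=block,
                                  missing_fraction={"batA": nmiss / width,
                                                    "batB": 0.0})
            cands.append(c)
        exons = [_iv(0, 40)]
        out = apply_filters(cands, exons, ["batA", "batB"], max_exon_frac=0.5)
        for c in out:
            assert c.missing_fraction["batA"] <= 0.5
            assert c.exon_fraction <= 0.5
            assert c.focal_taxa_count >= 1


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestRbh:
    def _setup(self, seed=15):
        rng = np.random.default_rng(seed)
        genome = {"chr1": _random_seq(rng, 2000)}
        iv = _iv(800, 1100, name="c0")
        block = MultipleAlignment({"ref": genome["chr1"], "batA": genome["chr1"]},
                                  "ref", "chr1", 0)
        c = CandidateEnhancer(interval=iv)
        unmask_species(c, [block], ["batA"])
        return rng, genome, c

    def test_exact_copy_accepted_and_row_matches_reference(self):
        rng, genome, c = self._setup()
        contig = genome["chr1"][700:1200]
        out, decisions = rbh_integrate(
            c, {"batC": {"ctg1": contig}}, genome)
        assert decisions[0].accepted
        assert out.alignment.seqs["batC"] == out.alignment.seqs["ref"]

    def test_symmetric_scores_on_exact_copy(self):
        rng, genome, c = self._setup()
        query = c.alignment.seqs["ref"].replace("-", "")
        aligner = _sw_aligner()
        fwd = aligner.align(query, genome["chr1"][700:1200])[0]
        rev = aligner.align(genome["chr1"][700:1200], query)[0]
        assert fwd.score == rev.score

    def test_no_hit_above_threshold_unchanged(self):
        rng, genome, c = self._setup()
        decoy = _random_seq(np.random.default_rng(99), 400)
        species_before = set(c.alignment.species)
        out, decisions = rbh_integrate(c, {"batC": {"d": decoy}}, genome)
        assert not decisions[0].accepted
        assert set(out.alignment.species) == species_before

    def test_paralogous_decoy_rejected_by_reverse_hit(self):
        """A contig copying a paralogous locus passes the forward e-value but
        its reverse best hit maps to the paralog, not the candidate."""
        rng = np.random.default_rng(16)
        seq = _random_seq(rng, 2000)
        core = seq[800:1100]
        # plant a diverged copy of the candidate elsewhere
        mutated = list(core)
        for i in rng.choice(len(core), size=30, replace=False):
            mutated[i] = "ACGT"[(("ACGT".index(mutated[i])) + 1) % 4]
        genome = {"chr1": seq[:1500] + "".join(mutated) + seq[1800:]}
        block = MultipleAlignment({"ref": genome["chr1"],
                                   "batA": genome["chr1"]}, "ref", "chr1", 0)
        c = CandidateEnhancer(interval=_iv(800, 1100, name="c0"))
        unmask_species(c, [block], ["batA"])
        # contig is an exact copy of the PARALOG at [1500, 1800)
        contig = genome["chr1"][1500:1800]
        out, decisions = rbh_integrate(c, {"batC": {"par": contig}}, genome)
        d = decisions[0]
        assert not d.accepted
        assert d.reverse_interval is not None
        assert d.reverse_interval.overlaps(_iv(1500, 1800))
        assert not d.reverse_interval.overlaps(c.interval)

    def test_empty_database_noop(self):
        _, genome, c = self._setup()
        out, decisions = rbh_integrate(c, {"batC": {}}, genome)
        assert not decisions[0].accepted
        assert "empty" in decisions[0].reason


class TestEvalueStatistics:
    def test_lambda_solves_its_equation(self):
        lam = karlin_altschul_lambda(1.0, -2.0, gc=0.5)
        lhs = 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam)
        assert lhs == pytest.approx(1.0, abs=1e-9)

    def test_evalue_decreases_with_score(self):
        evs = [sw_evalue(s, 300, 10_000) for s in (20, 50, 100)]
        assert evs[0] > evs[1] > evs[2]

    def test_seed_index_finds_planted_segment(self):
        rng = np.random.default_rng(17)
        genome = {"c1": _random_seq(rng, 5000), "c2": _random_seq(rng, 5000)}
        query = genome["c2"][3000:3400]
        hit = GenomeSeedIndex(genome).best_local(_sw_aligner(), query)
        assert hit is not None
        chrom, top, off = hit
        assert chrom == "c2"
        assert off + int(top.aligned[1][0][0]) == 3000
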