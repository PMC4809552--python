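"""Reference-anchored multiple alignment blocks and MAF I/O.

A block stores one gapped row per species plus the reference species' genomic
placement. MAF ``s`` lines use the ``species.chrom`` source convention; starts
are 0-based and the reference row is written first. Reading and writing go
through Bio.AlignIO's MAF support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import encode_sequence


@dataclass
class MultipleAlignment:
    """One alignment block keyed by species name.

    ``seqs`` maps species -> gapped sequence over {A,C,G,T,-,N}; all rows have
    equal length. ``start`` is the 0-based reference coordinate of the block's
    first reference base; the reference row's non-gap count equals the length
    of the reference interval the block maps to.
    """

    seqs: dict[str, str]
    ref: str
    chrom: str
    start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.ref not in self.seqs:
            raise ValueError(f"reference species {self.ref!r} has no row")
        widths = {len(s) for s in self.seqs.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment rows: widths {sorted(widths)}")

    @property
    def ncols(self) -> int:
        return len(self.seqs[self.ref])

    @property
    def species(self) -> list[str]:
        return list(self.seqs)

    @property
    def ref_length(self) -> int:
        return sum(1 for c in self.seqs[self.ref] if c != "-")

    @property
    def end(self) -> int:
        """Reference end coordinate (half-open)."""
        return self.start + self.ref_length

    def codes(self) -> dict[str, np.ndarray]:
        """uint8 state codes per row (A=0..T=3, missing=4)."""
        return {s: encode_sequence(seq) for s, seq in self.seqs.items()}

    def ref_positions(self) -> np.ndarray:
        """Reference coordinate assigned to every column.

        Columns where the reference row is gapped take the coordinate of the
        preceding reference base (the block start for leading gaps).
        """
        ref_codes = np.frombuffer(self.seqs[self.ref].encode(), dtype=np.uint8)
        nongap = ref_codes != ord("-")
        idx = np.cumsum(nongap) - 1          # ref-base ordinal per column
        np.clip(idx, 0, None, out=idx)
        return self.start + idx

    def column_at(self, col: int) -> dict[str, str]:
        return {s: seq[col] for s, seq in self.seqs.items()}

    def missing_fraction(self, species: str) -> float:
        """Fraction of columns where `species` is gap/N (1.0 if row absent)."""
        if species not in self.seqs or self.ncols == 0:
            return 1.0
        codes = encode_sequence(self.seqs[species])
        return float((codes == 4).mean())

    def drop_species(self, names: Iterable[str]) -> "MultipleAlignment":
        names = set(names)
        if self.ref in names:
            raise ValueError("cannot drop the reference row")
        return replace(self, seqs={s: q for s, q in self.seqs.items() if s not in names})

    def with_row(self, species: str, seq: str) -> "MultipleAlignment":
        if len(seq) != self.ncols:
            raise ValueError("row width mismatch")
        new = dict(self.seqs)
        new[species] = seq
        return replace(self, seqs=new)

    def slice_ref(self, start: int, end: int) -> "MultipleAlignment":
        """Columns whose assigned reference coordinate falls in [start, end)."""
        if start < self.start or end > self.end or end <= start:
            raise ValueError(
                f"[{start}, {end}) outside block [{self.start}, {self.end})"
            )
        pos = self.ref_positions()
        ref_codes = np.frombuffer(self.seqs[self.ref].encode(), dtype=np.uint8)
        keep = (pos >= start) & (pos < end)
        # leading reference-gap columns belong to the previous base, drop them
        # from the slice unless that base itself is inside the slice
        cols = np.flatnonzero(keep)
        seqs = {s: "".join(q[c] for c in cols) for s, q in self.seqs.items()}
        return MultipleAlignment(seqs, self.ref, self.chrom, start, self.strand)


def slice_blocks(blocks: Sequence[MultipleAlignment], chrom: str,
                 start: int, end: int) -> MultipleAlignment:
    """Extract the alignment of a reference interval that may span blocks.

    Blocks must be non-overlapping on the reference. Species absent from a
    contributing block are padded with gaps; uncovered reference bases are
    padded with the reference base as ``N`` (unknown) for every species.
    """
    parts: list[MultipleAlignment] = []
    for b in sorted(blocks, key=lambda b: b.start):
        if b.chrom != chrom or b.end <= start or b.start >= end:
            continue
        parts.append(b.slice_ref(max(start, b.start), min(end, b.end)))
    if not parts:
        raise ValueError(f"no alignment covers {chrom}:{start}-{end}")
    ref = parts[0].ref
    species = []
    for p in parts:
        for s in p.species:
            if s not in species:
                species.append(s)
    out = {s: [] for s in species}
    cursor = start
    for p in parts:
        if p.start > cursor:  # uncovered gap on the reference
            pad = "N" * (p.start - cursor)
            for s in species:
                out[s].append(pad if s == ref else "-" * len(pad))
        for s in species:
            out[s].append(p.seqs.get(s, "-" * p.ncols))
        cursor = p.end
    if cursor < end:
        pad = "N" * (end - cursor)
        for s in species:
            out[s].append(pad if s == ref else "-" * len(pad))
    return MultipleAlignment({s: "".join(v) for s, v in out.items()}, ref, chrom, start)


# ---------------------------------------------------------------------------
# MAF I/O
# ---------------------------------------------------------------------------


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
    else:
        sp, chrom = src, src
    return sp, chrom


def read_maf(path: str | Path) -> list[MultipleAlignment]:
    """Read MAF blocks; the first row of each block is taken as the reference."""
    blocks: list[MultipleAlignment] = []
    for msa in AlignIO.parse(str(path), "maf"):
        seqs: dict[str, str] = {}
        ref = chrom = None
        start = 0
        for rec in msa:
            sp, src_chrom = _split_src(rec.id)
            seqs[sp] = str(rec.seq).upper()
            if ref is None:
                ref, chrom = sp, src_chrom
                start = int(rec.annotations["start"])
                if rec.annotations.get("strand", 1) not in (1, "+"):
                    raise ValueError("reference row must be on the + strand")
        blocks.append(MultipleAlignment(seqs, ref, chrom, start))
    return blocks


def write_maf(blocks: Sequence[MultipleAlignment], path: str | Path,
              src_sizes: Mapping[str, int] | None = None) -> None:
    """Write blocks as MAF (reference row first, + strand coordinates)."""
    src_sizes = src_sizes or {}
    msas = []
    for b in blocks:
        records = []
        order = [b.ref] + [s for s in b.species if s != b.ref]
        for sp in order:
            seq = b.seqs[sp]
            size = sum(1 for c in seq if c != "-")
            rec = SeqRecord(Seq(seq), id=f"{sp}.{b.chrom}" if sp == b.ref else f"{sp}.contig")
            rec.annotations = {
                "start": b.start if sp == b.ref else 0,
                "size": size,
                "strand": 1,
                "srcSize": src_sizes.get(sp, max(b.end, size)),
            }
            records.append(rec)
        msas.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")
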