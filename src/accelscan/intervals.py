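"""Genomic intervals and BED I/O.

All coordinates are 0-based half-open throughout the package; BED files are
read and written natively in that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on a named sequence.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) name.
    start, end : int
        0-based half-open bounds; ``end > start`` and ``start >= 0``.
    name : str
        Feature name (BED column 4); empty allowed.
    score : float
        Feature score (BED column 5).
    strand : str
        '+', '-' or '.' when strand is irrelevant.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.name!r}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) for {self.name!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; raises ValueError naming the offending line."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else "",
                    score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, ndigits: int = 2) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{round(iv.score, ndigits)}\t{iv.strand}\n"
            )


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_overlapping(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse a set of intervals into disjoint sorted intervals covering the
    same bases (book-ended intervals are joined)."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(replace(iv))
    return out


def covered_bases(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_overlapping(intervals))


def overlap_fraction(target: GenomicInterval, others: Sequence[GenomicInterval]) -> float:
    """Fraction of `target` bases covered by the union of `others`."""
    clipped = [
        GenomicInterval(target.chrom, max(o.start, target.start), min(o.end, target.end))
        for o in others
        if target.overlaps(o)
    ]
    if not clipped:
        return 0.0
    return covered_bases(clipped) / len(target)
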