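"""Post-hoc characterization of accelerated regions: TSS distances, gene
deserts, spatial clustering, and gene-proximity enrichment.

The clustering statistic is the median same-chromosome nearest-neighbor
distance between element midpoints, compared with sets of the same size drawn
without replacement from the candidate pool; the proximity test builds a
2x2 near/far table against a supplied TSS list and resamples candidate sets
the same way.  Both report add-one permutation p-values (never exactly 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval


def tss_distance(element: GenomicInterval, tss: Sequence[GenomicInterval]) -> float:
    """Distance (bp) to the closest TSS on the element's chromosome.

    0 if a TSS lies inside (or abuts) the element, otherwise the interval gap
    to the nearest element edge; ``inf`` when the chromosome has no TSS.
    The gap convention is symmetric under coordinate reflection.
    """
    best = math.inf
    for t in tss:
        if t.chrom != element.chrom:
            continue
        d = max(0, element.start - t.end, t.start - element.end)
        best = min(best, float(d))
    return best


def gene_desert_flag(element: GenomicInterval, tss: Sequence[GenomicInterval],
                     radius: int = 500_000) -> bool:
    """True iff every TSS on the chromosome is strictly more than `radius` bp
    away in either direction (a TSS exactly at the radius disqualifies)."""
    for t in tss:
        if t.chrom != element.chrom:
            continue
        if max(0, element.start - t.end, t.start - element.end) <= radius:
            return False
    return True


def _median_nn_distance(elements: Sequence[GenomicInterval]) -> float:
    """Median over elements of the distance to the nearest other element
    midpoint on the same chromosome; elements with no same-chromosome
    neighbor are excluded."""
    by_chrom: dict[str, list[float]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el.midpoint)
    dists: list[float] = []
    for mids in by_chrom.values():
        if len(mids) < 2:
            continue
        arr = np.sort(np.asarray(mids))
        gap_prev = np.r_[np.inf, np.diff(arr)]
        gap_next = np.r_[np.diff(arr), np.inf]
        dists.extend(np.minimum(gap_prev, gap_next))
    if not dists:
        return math.inf
    return float(np.median(dists))


def clustering_permutation_test(bars: Sequence[GenomicInterval],
                                candidates: Sequence[GenomicInterval],
                                n_perm: int = 1000,
                                seed: int | None = None) -> tuple[float, float]:
    """Do the called elements cluster more densely than random candidate sets?

    Statistic: median same-chromosome nearest-neighbor midpoint distance.
    Null: |bars| candidates drawn uniformly without replacement, `n_perm`
    times.  Returns (p, observed statistic) with the add-one rule
    p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if len(bars) < 2:
        raise ValueError("need at least 2 called elements")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = {c.name for c in candidates}
    if not all(b.name in names for b in bars):
        raise ValueError("called elements must be a subset of the candidates")
    observed = _median_nn_distance(bars)
    rng = np.random.default_rng(seed)
    pool = list(candidates)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(pool), size=len(bars), replace=False)
        if _median_nn_distance([pool[i] for i in idx]) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1), observed


@dataclass
class EnrichmentResult:
    """Near/far 2x2 association between called and uncalled candidates."""

    near_bar: int
    far_bar: int
    near_other: int
    far_other: int
    odds_ratio: float
    pvalue: float
    n_perm: int

    def __post_init__(self) -> None:
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be nonnegative")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("permutation p must lie in (0, 1]")


def _near_flags(elements: Sequence[GenomicInterval],
                gene_tss: Sequence[GenomicInterval], window: int) -> np.ndarray:
    return np.array([tss_distance(el, gene_tss) <= window for el in elements])


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with the Haldane-Anscombe 0.5 correction when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def proximity_enrichment(bars: Sequence[GenomicInterval],
                         candidates: Sequence[GenomicInterval],
                         gene_tss: Sequence[GenomicInterval],
                         window: int = 1_000_000,
                         n_perm: int = 1000,
                         seed: int | None = None) -> EnrichmentResult:
    """Enrichment of called elements near a gene list, versus candidate draws.

    "Near" means within `window` bp of any listed TSS.  The odds ratio comes
    from the (called x near) 2x2 table over all candidates; the permutation p
    resamples |bars| candidates without replacement and counts null odds
    ratios at least as large (one-sided enrichment, add-one rule).
    """
    if not gene_tss:
        raise ValueError("empty gene TSS list")
    bar_names = {b.name for b in bars}
    if not bar_names <= {c.name for c in candidates}:
        raise ValueError("called elements must be a subset of the candidates")
    near = _near_flags(candidates, gene_tss, window)
    is_bar = np.array([c.name in bar_names for c in candidates])
    a = int((near & is_bar).sum())
    b = int((~near & is_bar).sum())
    c = int((near & ~is_bar).sum())
    d = int((~near & ~is_bar).sum())
    observed = odds_ratio_2x2(a, b, c, d)

    rng = np.random.default_rng(seed)
    k = int(is_bar.sum())
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(candidates), size=k, replace=False)
        sel = np.zeros(len(candidates), dtype=bool)
        sel[idx] = True
        orr = odds_ratio_2x2(int((near & sel).sum()), int((~near & sel).sum()),
                             int((near & ~sel).sum()), int((~near & ~sel).sum()))
        if orr >= observed - 1e-12:
            hits += 1
    return EnrichmentResult(a, b, c, d, observed, (1 + hits) / (n_perm + 1), n_perm)


def summary_report(bars: Sequence[GenomicInterval],
                   tss: Sequence[GenomicInterval],
                   desert_radius: int = 500_000) -> dict:
    """Headline distance summaries for a called element set."""
    dists = [tss_distance(b, tss) for b in bars]
    n = len(bars)
    finite = [d for d in dists if math.isfinite(d)]
    return {
        "n_elements": n,
        "mean_length": float(np.mean([len(b) for b in bars])) if n else 0.0,
        "frac_tss_gt_20kb": (sum(d > 20_000 for d in dists) / n) if n else 0.0,
        "frac_tss_gt_100kb": (sum(d > 100_000 for d in dists) / n) if n else 0.0,
        "n_gene_desert": sum(gene_desert_flag(b, tss, desert_radius) for b in bars),
        "median_tss_distance": float(np.median(finite)) if finite else math.inf,
    }
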