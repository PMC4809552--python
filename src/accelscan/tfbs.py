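"""PWM scanning with exact null score distributions and the two-sequence
binding-site count-divergence test.

Hits are called by log-odds score against an exact background score
distribution computed by dynamic programming on a discretized score grid
(granularity 1e-3 bits), with per-sequence Benjamini-Hochberg control of the
hit FDR.  Gain/loss of sites between two sequences (e.g. a reconstructed
ancestor versus an extant ortholog) is tested with a conditional exact test:
given the total hit count K = k_a + k_b, under the null of equal per-window
hit rates k_a ~ Binomial(K, n_a / (n_a + n_b)) where the n's count scannable
position-strand windows.  This is a deliberate simplification of the
published correlated-binomial treatment of overlapping windows; see the
methods note.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .acceleration import bh_fdr
from .phylo import encode_sequence

GRANULARITY_BITS = 1e-3
MAX_PWM_WIDTH = 25

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWM:
    """Position probability matrix with background.

    `matrix` has shape (4, w) over rows A, C, G, T and columns positions;
    a pseudocount is applied at construction so every probability is positive.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.width < 1:
            raise ValueError("PWM matrix must be 4 x w with w >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    pseudocount: float = 0.01,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, matrix, bg)

    def log_odds_bits(self) -> np.ndarray:
        """Per-position log2(p / background), shape (4, w)."""
        return np.log2(self.matrix / self.background[:, None])

    def int_scores(self, granularity: float = GRANULARITY_BITS) -> np.ndarray:
        """Log-odds discretized to integer grid units (shape (4, w))."""
        return np.rint(self.log_odds_bits() / granularity).astype(np.int64)

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1]
        return PWM(self.motif_id, rc.copy(), self.background.copy())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def read_jaspar(path: str | Path, pseudocount: float = 0.01,
                background: np.ndarray | None = None) -> list[PWM]:
    """Read JASPAR-style PFM text (count matrices) via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.matrix_id or m.name
            out.append(PWM.from_counts(name, counts, pseudocount, background))
    return out


def read_meme(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read MEME minimal-format motifs via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg = np.array([record.background[b] for b in "ACGT"], dtype=float)
    for m in record:
        probs = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
        # re-apply pseudocount on the probability scale to keep log-odds finite
        probs = probs + pseudocount
        probs /= probs.sum(axis=0, keepdims=True)
        out.append(PWM(m.name, probs, bg))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR PFM text (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{pwm.matrix[bi, j] * scale:.2f}"
                                 for j in range(pwm.width))
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Exact score distribution
# ---------------------------------------------------------------------------


@dataclass
class ScoreDistribution:
    """Exact distribution of the discretized window log-odds score under the
    background model, as (integer score offset, probability array)."""

    min_score: int
    probs: np.ndarray
    granularity: float = GRANULARITY_BITS

    def __post_init__(self) -> None:
        self._sf = np.cumsum(self.probs[::-1])[::-1]

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.probs) - 1

    def sf(self, int_score: int) -> float:
        """P(score >= int_score) under the background."""
        idx = int_score - self.min_score
        if idx <= 0:
            return 1.0
        if idx >= len(self.probs):
            return 0.0
        return float(self._sf[idx])

    def support(self) -> np.ndarray:
        return self.min_score + np.flatnonzero(self.probs > 0)


def exact_score_distribution(pwm: PWM,
                             granularity: float = GRANULARITY_BITS) -> ScoreDistribution:
    """Column-wise convolution of per-position score distributions.

    The integer score of a window is the sum over columns of the discretized
    per-base log-odds; under the background model columns are independent, so
    the distribution is an exact convolution on the integer grid.
    """
    if pwm.width > MAX_PWM_WIDTH:
        raise ValueError(f"PWM width {pwm.width} exceeds cap {MAX_PWM_WIDTH}")
    scores = pwm.int_scores(granularity)
    bg = pwm.background
    probs = np.array([1.0])
    min_score = 0
    for j in range(pwm.width):
        col = scores[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(probs) + (hi - lo))
        for b in range(4):
            off = int(col[b]) - lo
            new[off:off + len(probs)] += bg[b] * probs
        probs = new
        min_score += lo
    return ScoreDistribution(min_score, probs, granularity)


# ---------------------------------------------------------------------------
# Scanning and hit calling
# ---------------------------------------------------------------------------


@dataclass
class TfbsHit:
    """One called binding-site hit."""

    sequence_id: str
    offset: int          # 0-based, in the scanned sequence's coordinates
    strand: str
    score_bits: float
    pvalue: float
    qvalue: float


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(integer score, validity) for every window start; windows containing
    N/gap are invalid."""
    w = int_scores.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid_base = codes < 4
    safe = np.where(valid_base, codes, 0)
    per_pos = np.empty((len(codes), w), dtype=np.int64)
    for j in range(w):
        per_pos[:, j] = int_scores[safe, j]
    scores = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(w):
        scores += per_pos[j:j + n, j]
        ok &= valid_base[j:j + n]
    return scores, ok


def scannable_windows(seq: str, width: int, both_strands: bool = True) -> int:
    """Number of valid (N-free) position-strand windows in a sequence."""
    codes = encode_sequence(seq)
    _, ok = _window_scores(codes, np.zeros((5, width), dtype=np.int64)[:4])
    n = int(ok.sum())
    return 2 * n if both_strands else n


def scan_and_call(seq: str, pwm: PWM, hit_fdr: float = 0.01,
                  sequence_id: str = "seq",
                  dist: ScoreDistribution | None = None) -> list[TfbsHit]:
    """Scan both strands, attach exact p-values per window and call hits at
    q <= `hit_fdr` after BH over all windows of this sequence."""
    w = pwm.width
    codes = encode_sequence(seq)
    if len(codes) < w:
        return []
    if dist is None:
        dist = exact_score_distribution(pwm)
    int_scores = pwm.int_scores(dist.granularity)
    rc_scores = pwm.reverse_complement().int_scores(dist.granularity)

    fwd, fwd_ok = _window_scores(codes, int_scores)
    rev, rev_ok = _window_scores(codes, rc_scores)

    windows: list[tuple[int, str, int]] = []
    for i in np.flatnonzero(fwd_ok):
        windows.append((int(i), "+", int(fwd[i])))
    for i in np.flatnonzero(rev_ok):
        windows.append((int(i), "-", int(rev[i])))
    if not windows:
        return []
    pvals = np.array([dist.sf(s) for (_, _, s) in windows])
    qvals = bh_fdr(pvals)
    hits = [
        TfbsHit(sequence_id, off, strand, s * dist.granularity,
                float(p), float(q))
        for (off, strand, s), p, q in zip(windows, pvals, qvals)
        if q <= hit_fdr
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Count-divergence test
# ---------------------------------------------------------------------------


def motif_count_test(k_a: int, n_a: int, k_b: int, n_b: int) -> tuple[float, str]:
    """Conditional exact test of equal per-window hit rates.

    Given K = k_a + k_b, under the null k_a ~ Binomial(K, n_a/(n_a+n_b)); the
    two-sided p-value sums the probabilities of all outcomes no more probable
    than the observed one.  Returns (p, direction) with direction the sign of
    the rate difference in sequence a: 'gain', 'loss' or 'none'.
    """
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    if n_a == 0 and n_b == 0:
        raise ValueError("no scannable windows on either side")
    K = k_a + k_b
    rate_a = k_a / n_a if n_a else 0.0
    rate_b = k_b / n_b if n_b else 0.0
    direction = "gain" if rate_a > rate_b else ("loss" if rate_a < rate_b else "none")
    if K == 0:
        return 1.0, "none"
    p0 = n_a / (n_a + n_b)
    pmf = binom.pmf(np.arange(K + 1), K, p0)
    p_obs = pmf[k_a]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, max(p, np.nextafter(0, 1))), direction


@dataclass
class MotifCountResult:
    motif_id: str
    element_id: str      # "pooled" in pooled mode
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    pvalue: float
    qvalue: float
    direction: str


def divergence_screen(pairs: Sequence[tuple[str, str, str]],
                      pwms: Sequence[PWM],
                      pooled: bool = True,
                      hit_fdr: float = 0.01,
                      screen_fdr: float = 0.05) -> pd.DataFrame:
    """Gain/loss screen over (element id, sequence a, sequence b) pairs.

    Sequence a is conventionally the reconstructed ancestor and b the extant
    ortholog.  In pooled mode hit and window counts are summed over elements
    before one test per motif; otherwise each (element, motif) pair is tested.
    BH runs across all tests; `significant` marks q < `screen_fdr`.
    """
    if not pwms:
        raise ValueError("empty motif set")
    rows: list[MotifCountResult] = []
    for pwm in pwms:
        dist = exact_score_distribution(pwm)
        counts = []
        for elem_id, seq_a, seq_b in pairs:
            k_a = len(scan_and_call(seq_a, pwm, hit_fdr, elem_id, dist))
            k_b = len(scan_and_call(seq_b, pwm, hit_fdr, elem_id, dist))
            n_a = scannable_windows(seq_a, pwm.width)
            n_b = scannable_windows(seq_b, pwm.width)
            counts.append((elem_id, k_a, n_a, k_b, n_b))
        if pooled:
            k_a = sum(c[1] for c in counts)
            n_a = sum(c[2] for c in counts)
            k_b = sum(c[3] for c in counts)
            n_b = sum(c[4] for c in counts)
            if n_a == 0 and n_b == 0:
                continue
            p, direction = motif_count_test(k_a, n_a, k_b, n_b)
            rows.append(MotifCountResult(pwm.motif_id, "pooled",
                                           k_a, n_a, k_b, n_b, p, np.nan, direction))
        else:
            for elem_id, k_a, n_a, k_b, n_b in counts:
                if n_a == 0 and n_b == 0:
                    continue
                p, direction = motif_count_test(k_a, n_a, k_b, n_b)
                rows.append(MotifCountResult(pwm.motif_id, elem_id,
                                               k_a, n_a, k_b, n_b, p, np.nan, direction))
    df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        return df
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < screen_fdr
    return df
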