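"""Promoter extraction, composition, and PWM scanning with exact p-values.

Promoters are the 500 bp upstream of a (sense or antisense) TSS, reported
5'->3' in the anchor's strand frame.  PWM matches are scored as log-odds in
bits against a 0-order background, and p-values are exact: the full score
distribution of a background-drawn W-mer is computed by dynamic programming
over a discretized score grid (default bin 1e-4 bits), and a match's p-value
is the survival function at its score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeSequence, reverse_complement
from .synthetic import IUPAC

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class Pwm:
    """Position probability matrix (W x 4, columns A,C,G,T) + background."""

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a (W, 4) matrix with W >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9) or np.any(self.background <= 0):
            raise ValueError("background must be a positive distribution over ACGT")
        if np.any(self.probs <= 0):
            raise ValueError("probabilities must be strictly positive (apply a pseudocount)")
        self._dp_cache: dict[float, tuple] = {}

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def log_odds(self) -> np.ndarray:
        """(W, 4) log2(p / background) scoring matrix, in bits."""
        return np.log2(self.probs / self.background[None, :])

    def with_background(self, background: np.ndarray) -> "Pwm":
        return Pwm(self.probs.copy(), np.asarray(background, dtype=float), self.pseudocount)

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        bg = np.full(4, 0.25) if background is None else background
        return cls(probs, bg, pseudocount)

    @classmethod
    def from_consensus(cls, consensus: str, pseudocount: float = 0.25,
                       background: np.ndarray | None = None) -> "Pwm":
        """Build a PWM from an IUPAC consensus, uniform within each code."""
        counts = np.zeros((len(consensus), 4))
        for i, code in enumerate(consensus.upper()):
            bases = IUPAC[code]
            for b in bases:
                counts[i, _BASE_INDEX[b]] = 1.0 / len(bases)
        return cls.from_counts(counts, pseudocount, background)

    @classmethod
    def from_jaspar_pfm(cls, path, pseudocount: float = 0.25) -> "Pwm":
        """JASPAR PFM: optional '>' header, then four rows (A, C, G, T)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                line = line.split("[", 1)[-1].split("]", 1)[0]
                if line and line[0] in "ACGT":
                    line = line[1:]
                rows.append([float(x) for x in line.split()])
        if len(rows) != 4:
            raise ValueError(f"{path}: expected 4 base rows, found {len(rows)}")
        return cls.from_counts(np.array(rows).T, pseudocount)

    @classmethod
    def from_meme(cls, path) -> "Pwm":
        """MEME minimal format: first letter-probability matrix in the file."""
        probs = []
        with open(path) as fh:
            in_matrix = False
            for line in fh:
                s = line.strip()
                if s.startswith("letter-probability matrix"):
                    in_matrix = True
                    continue
                if in_matrix:
                    parts = s.split()
                    if len(parts) == 4:
                        probs.append([float(x) for x in parts])
                    elif probs:
                        break
        if not probs:
            raise ValueError(f"{path}: no letter-probability matrix found")
        p = np.array(probs)
        p = np.clip(p, 1e-6, None)
        p = p / p.sum(axis=1, keepdims=True)
        return cls(p)

    # -- exact score distribution ------------------------------------------

    _EXACT_WIDTH_LIMIT = 10  # up to 4^10 partial sums: exact DP stays cheap

    def _exact_dist(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact score distribution: sorted attainable totals + survival fn.

        Dynamic program over partial sums, merging equal values at each step;
        feasible because a column contributes only four score levels.
        """
        if "exact" in self._dp_cache:
            return self._dp_cache["exact"]
        lod = self.log_odds()
        scores = np.zeros(1)
        probs = np.ones(1)
        for i in range(self.width):
            scores = (scores[:, None] + lod[i][None, :]).ravel()
            probs = (probs[:, None] * self.background[None, :]).ravel()
            scores, inv = np.unique(scores, return_inverse=True)
            probs = np.bincount(inv, weights=probs)
        sf = np.cumsum(probs[::-1])[::-1]
        self._dp_cache["exact"] = (scores, sf)
        return scores, sf

    def _grid_dist(self, bin_width: float) -> tuple[int, np.ndarray]:
        """Discretized score distribution for wide motifs: (grid base, sf)."""
        key = ("grid", bin_width)
        if key in self._dp_cache:
            return self._dp_cache[key]
        ints = np.round(self.log_odds() / bin_width).astype(np.int64)
        base = int(ints.min(axis=1).sum())
        pmf = np.ones(1)
        used = 0
        for i in range(self.width):
            col = ints[i] - ints[i].min()
            width_i = int(col.max())
            new = np.zeros(used + width_i + 1)
            for b in range(4):
                new[col[b]: col[b] + used + 1] += pmf * self.background[b]
            used += width_i
            pmf = new
        sf = np.cumsum(pmf[::-1])[::-1]
        self._dp_cache[key] = (base, sf)
        return base, sf

    def score_pvalue(self, score: float, bin_width: float = 1e-4) -> float:
        """P(log-odds of a background-drawn W-mer >= score).

        Exact for widths up to 10; discretized (grid ``bin_width`` bits, with
        one tick of slack per position so no qualifying W-mer is dropped)
        beyond that.
        """
        if self.width <= self._EXACT_WIDTH_LIMIT:
            scores, sf = self._exact_dist()
            idx = int(np.searchsorted(scores, score - 1e-9, side="left"))
            return float(sf[idx]) if idx < sf.size else 0.0
        base, sf = self._grid_dist(bin_width)
        idx = int(np.round(score / bin_width)) - self.width - base
        if idx <= 0:
            return 1.0
        if idx >= sf.size:
            return float(sf[-1]) if sf[-1] > 0 else 0.0
        return float(sf[idx])

    def score_threshold(self, p_threshold: float, bin_width: float = 1e-4) -> float:
        """Smallest attainable score whose p-value is <= ``p_threshold``.

        Above the maximum attainable score when even the best match is less
        surprising than the threshold (no window can ever pass).
        """
        if self.width <= self._EXACT_WIDTH_LIMIT:
            scores, sf = self._exact_dist()
            ok = np.flatnonzero(sf <= p_threshold)
            return float(scores[ok[0]]) if ok.size else float(scores[-1] + 1.0)
        base, sf = self._grid_dist(bin_width)
        ok = np.flatnonzero(sf <= p_threshold)
        if not ok.size:
            return float((base + sf.size) * bin_width + 1.0)
        return float((base + ok[0]) * bin_width)


def pwm_score_pvalue(pwm: Pwm, score: float, bin_width: float = 1e-4) -> float:
    return pwm.score_pvalue(score, bin_width)


# ---------------------------------------------------------------------------
# Promoters


@dataclass
class PromoterSeq:
    anchor: tuple[str, int, str]
    chrom: str
    genomic_start: int
    genomic_end: int
    seq: str                      # 5'->3' in the anchor's strand frame

    def __len__(self) -> int:
        return len(self.seq)


def extract_promoters(anchors: list[tuple[str, int, str]], genome: GenomeSequence,
                      length: int = 500) -> list[PromoterSeq]:
    """Upstream windows of each anchor, reported in the anchor strand frame.

    A + anchor at p yields genomic [p-length, p) forward; a - anchor yields
    genomic [p+1, p+1+length) reverse-complemented.  Windows are clipped at
    chromosome ends (logged); anchors with zero extractable bases are
    skipped with a warning.
    """
    out = []
    clipped = 0
    for chrom, pos, strand in anchors:
        L = genome.length(chrom)
        if strand == "+":
            s, e = max(pos - length, 0), min(pos, L)
        else:
            s, e = max(pos + 1, 0), min(pos + 1 + length, L)
        if e <= s:
            warnings.warn(f"anchor {chrom}:{pos}:{strand}: no extractable promoter bases")
            continue
        if e - s < length:
            clipped += 1
        seq = genome.fetch(chrom, s, e)
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(PromoterSeq((chrom, pos, strand), chrom, s, e, seq))
    if clipped:
        logger.info("extract_promoters: %d windows clipped at chromosome ends", clipped)
    return out


def gc_content(sequences: list[str]) -> tuple[list[float], float]:
    """Per-sequence and mean GC%%; N excluded from both counts."""
    per = []
    for s in sequences:
        acgt = sum(s.count(b) for b in _BASES)
        per.append(float("nan") if acgt == 0
                   else 100.0 * (s.count("G") + s.count("C")) / acgt)
    vals = [v for v in per if v == v]
    return per, (float(np.mean(vals)) if vals else float("nan"))


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class MotifHit:
    seq_index: int
    offset: int                    # 0-based match start on the scanned sequence
    strand: str                    # relative to the scanned sequence
    score: float                   # log-odds, bits
    pvalue: float


def estimate_background(sequences: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in sequences:
        for i, b in enumerate(_BASES):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts += 1.0  # avoid zero background on degenerate input
    return counts / counts.sum()


def scan_pwm(sequences: list[str], pwm: Pwm, p_threshold: float = 1e-4,
             strands: str = "both", background="sequence-set",
             bin_width: float = 1e-4) -> list[MotifHit]:
    """All motif matches with p <= threshold across the sequence set.

    Windows containing N are skipped.  ``background`` is "uniform",
    "sequence-set" (0-order frequencies estimated from the scanned
    sequences, the FIMO default family), or an explicit length-4 frequency
    vector over ACGT.  Minus-strand hits score the reverse complement of the
    window; their offset is still the window start on the given sequence.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"unknown strands mode {strands!r}")
    if isinstance(background, str):
        if background == "sequence-set":
            pwm = pwm.with_background(estimate_background(sequences))
        elif background != "uniform":
            raise ValueError(f"unknown background mode {background!r}")
    else:
        pwm = pwm.with_background(np.asarray(background, dtype=float))

    W = pwm.width
    threshold = pwm.score_threshold(p_threshold, bin_width)
    lodds = pwm.log_odds()

    # N gets -inf so any window containing it is excluded
    fwd = np.hstack([lodds, np.full((W, 1), -np.inf)])
    rc = fwd[::-1, [3, 2, 1, 0, 4]]

    hits = []
    jj = np.arange(W)
    for si, s in enumerate(sequences):
        if len(s) < W:
            continue
        x = _encode(s)
        win = np.lib.stride_tricks.sliding_window_view(x, W)
        specs = [("+", fwd)]
        if strands == "both":
            specs.append(("-", rc))
        for strand, mat in specs:
            totals = mat[jj, win].sum(axis=1)
            for o in np.flatnonzero(totals >= threshold - 1e-9):
                score = float(totals[o])
                hits.append(MotifHit(si, int(o), strand, score,
                                     pwm.score_pvalue(score, bin_width)))
    return hits


def tata_fraction(promoters: list[PromoterSeq], pwm: Pwm,
                  p_threshold: float = 1e-4, **scan_kw) -> tuple[float, list[bool]]:
    """Fraction of promoters with >=1 PWM hit at the p-value threshold."""
    if not promoters:
        raise ValueError("no promoters given")
    hits = scan_pwm([p.seq for p in promoters], pwm, p_threshold, **scan_kw)
    has = [False] * len(promoters)
    for h in hits:
        has[h.seq_index] = True
    return sum(has) / len(has), has


def positional_histogram(hits: list[MotifHit], promoters: list[PromoterSeq],
                         pwm_width: int, hist_range: tuple[int, int] = (-500, -1),
                         bin_size: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of match centers relative to the TSS (position 0).

    A promoter of length L covers relative positions -L..-1; the match
    center is offset + floor(W/2) mapped into that frame.  Bins are
    half-open, anchored at the range start.
    """
    lo, hi = hist_range
    edges = np.arange(lo, hi + 2, bin_size)
    centers = []
    for h in hits:
        L = len(promoters[h.seq_index])
        rel = h.offset + pwm_width // 2 - L
        if lo <= rel <= hi:
            centers.append(rel)
    counts, _ = np.histogram(centers, bins=edges)
    return edges[:-1], counts
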