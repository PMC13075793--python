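"""Dyad calling, anchor-centered metaplots, phasing scores, and dyad GC.

MNase fragment midpoints approximate nucleosome dyads.  Midpoints are
smoothed with a Gaussian kernel into a density track; dyads are greedy local
maxima with a minimum separation just under one nucleosome footprint.
Metaplots are strand-framed profile matrices around arbitrary anchors, and
phasing is scored as the peak of the mean profile's normalized
autocorrelation within a plausible nucleosome-repeat band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_formats import FragmentSet, GeneModel, GenomeSequence, StrandedTrack

logger = logging.getLogger(__name__)

Anchor = tuple[str, int, str]  # chrom, position, strand


@dataclass
class DyadCalls:
    """Called dyads: (chrom, position, smoothed-density score)."""

    records: list[tuple[str, int, float]]

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for chrom, pos, _ in self.records:
            if chrom in prev and pos <= prev[chrom]:
                raise ValueError("dyad positions must be strictly increasing per chromosome")
            prev[chrom] = pos

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for c, p, _ in self.records if c == chrom])


@dataclass
class ProfileMatrix:
    """Anchors x relative-position values; +x is downstream in anchor frame."""

    anchor_ids: list
    rel_positions: np.ndarray
    values: np.ndarray
    normalization: str = "none"

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class PhasingScore:
    period: int | None
    amplitude: float
    autocorrelation: np.ndarray


def midpoint_density(fragments: FragmentSet, genome: GenomeSequence,
                     bandwidth: float = 20.0) -> dict[str, np.ndarray]:
    """Gaussian-smoothed fragment-midpoint density, one array per chromosome.

    The integral over the genome equals the fragment count, minus whatever
    kernel mass is truncated at chromosome edges.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    tracks = {c: np.zeros(genome.length(c)) for c in genome.seqs}
    if len(fragments) == 0:
        logger.warning("empty fragment set: returning zero density")
        return tracks
    for chrom, mid in fragments.midpoints():
        tracks[chrom][mid] += 1.0
    for chrom in tracks:
        tracks[chrom] = gaussian_filter1d(tracks[chrom], sigma=bandwidth,
                                          mode="constant", truncate=6.0)
    return tracks


def fragment_coverage(fragments: FragmentSet, genome: GenomeSequence) -> dict[str, np.ndarray]:
    """Per-base count of fragments covering each position (occupancy proxy)."""
    cov = {c: np.zeros(genome.length(c)) for c in genome.seqs}
    for chrom, s, e in fragments.records:
        cov[chrom][s:e] += 1.0
    return cov


def call_dyads(density: dict[str, np.ndarray], min_separation: int = 120,
               min_score: float = 0.0) -> DyadCalls:
    """Local maxima of the density, accepted greedily in descending score.

    A candidate within ``min_separation`` bp of an already accepted call is
    discarded; score ties break toward the leftmost position.
    """
    records = []
    for chrom in sorted(density):
        a = np.asarray(density[chrom], dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{chrom}: density must be finite")
        peaks, _ = find_peaks(a)
        peaks = peaks[a[peaks] > min_score]
        order = sorted(range(len(peaks)), key=lambda i: (-a[peaks[i]], peaks[i]))
        accepted: list[int] = []
        for i in order:
            p = peaks[i]
            if all(abs(p - q) >= min_separation for q in accepted):
                accepted.append(p)
        for p in sorted(accepted):
            records.append((chrom, int(p), float(a[p])))
    return DyadCalls(records)


def _track_array(track, chrom: str, strand: str) -> np.ndarray:
    if isinstance(track, StrandedTrack):
        return track.array(chrom, strand)
    return track[chrom]


def metaplot(track, anchors: list[Anchor], flank: int,
             normalization: str = "none") -> ProfileMatrix:
    """Anchor-centered profile matrix over +-flank bp.

    Rows are oriented so +x is downstream in the anchor's strand frame
    (minus-strand rows are reversed).  For a stranded track each anchor reads
    its own strand.  Anchors whose window leaves the chromosome are dropped
    (count logged).  ``normalization="library-mean-1"`` rescales the track to
    genome-wide mean 1 before extraction.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if normalization not in ("none", "library-mean-1"):
        raise ValueError(f"unknown normalization {normalization!r}")

    scale = 1.0
    if normalization == "library-mean-1":
        if isinstance(track, StrandedTrack):
            total = track.total()
            nbases = sum(a.size for a in track.plus.values()) * 2
        else:
            total = sum(float(a.sum()) for a in track.values())
            nbases = sum(a.size for a in track.values())
        if total <= 0:
            raise ValueError("cannot normalize an all-zero track")
        scale = nbases / total

    rows, ids = [], []
    dropped = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        a = _track_array(track, chrom, strand)
        if pos - flank < 0 or pos + flank + 1 > a.size:
            dropped += 1
            continue
        row = a[pos - flank: pos + flank + 1] * scale
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(i)
    if not rows:
        raise ValueError("no anchors retained within bounds")
    if dropped:
        logger.info("metaplot: dropped %d/%d out-of-bounds anchors", dropped, len(anchors))
    return ProfileMatrix(
        anchor_ids=ids,
        rel_positions=np.arange(-flank, flank + 1),
        values=np.vstack(rows),
        normalization=normalization,
    )


def plus_one_anchors(genes: list[GeneModel], dyads: DyadCalls,
                     search_window: int = 300) -> tuple[list[Anchor], int]:
    """First called dyad downstream of each gene's TSS, in its strand frame.

    Genes with no dyad within ``search_window`` bp downstream of (or at) the
    TSS are skipped; the skip count is returned alongside the anchors.
    """
    by_chrom = {c: dyads.positions(c) for c in {g.chrom for g in genes}}
    anchors: list[Anchor] = []
    skipped = 0
    for g in genes:
        pos = by_chrom.get(g.chrom, np.array([]))
        if g.strand == "+":
            cand = pos[(pos >= g.tss) & (pos <= g.tss + search_window)]
            hit = cand.min() if cand.size else None
        else:
            cand = pos[(pos <= g.tss) & (pos >= g.tss - search_window)]
            hit = cand.max() if cand.size else None
        if hit is None:
            skipped += 1
        else:
            anchors.append((g.chrom, int(hit), g.strand))
    return anchors, skipped


def phasing_score(profile: np.ndarray, period_band: tuple[int, int] = (100, 220)) -> PhasingScore:
    """Nucleosome-repeat periodicity of a mean profile.

    Amplitude is the maximum of the mean-subtracted profile's normalized
    autocorrelation within the period band; the period is the lag attaining
    it.  The score is invariant to affine rescaling of the profile; a flat
    profile has amplitude 0 and no period.
    """
    lo, hi = period_band
    x = np.asarray(profile, dtype=float)
    if x.size < 2 * hi:
        raise ValueError(f"profile length {x.size} < 2 x max period {hi}")
    x = x - x.mean()
    n = x.size
    denom = float(np.dot(x, x)) / n
    ac = np.zeros(hi + 1)
    if denom == 0:
        return PhasingScore(period=None, amplitude=0.0, autocorrelation=ac)
    for lag in range(1, hi + 1):
        # unbiased overlap normalization: a pure cosine scores 1 at its period
        ac[lag] = float(np.dot(x[:-lag], x[lag:])) / (n - lag) / denom
    band = ac[lo: hi + 1]
    amp = float(band.max())
    period = int(lo + np.argmax(band))
    return PhasingScore(period=period, amplitude=max(amp, 0.0), autocorrelation=ac)


def dyad_gc(dyads: DyadCalls, genome: GenomeSequence, halfwidth: int = 50) -> list[float]:
    """GC%% of the +-halfwidth window around each dyad.

    GC%% = (G+C)/(A+C+G+T) x 100; N bases are excluded from numerator and
    denominator.  Windows are clipped at chromosome ends; a window with no
    A/C/G/T at all yields NaN.
    """
    out = []
    for chrom, pos, _score in dyads.records:
        L = genome.length(chrom)
        s = max(pos - halfwidth, 0)
        e = min(pos + halfwidth, L)
        seq = genome.fetch(chrom, s, e)
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            out.append(float("nan"))
        else:
            out.append(100.0 * (seq.count("G") + seq.count("C")) / acgt)
    return out
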