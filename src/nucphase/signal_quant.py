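"""Fixed-window signal quantification around anchors.

The two windows of interest are the 200 bp downstream of an antisense TSS
(nascent antisense initiation, read on the anchor strand) and the 500 bp
upstream (nucleosome occupancy, unstranded).  Per-condition summaries of
those window means feed a cross-condition correlation of initiation against
occupancy; helpers for quartile stratification and genic/intergenic signal
partitioning round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneModel, StrandedTrack

logger = logging.getLogger(__name__)

Anchor = tuple[str, int, str]


def _window(pos: int, strand: str, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic [start, end) of the strand-framed window [rel_start, rel_end)."""
    if strand == "+":
        return pos + rel_start, pos + rel_end
    return pos - rel_end + 1, pos - rel_start + 1


def window_mean(track, anchors: list[Anchor], rel_start: int, rel_end: int,
                strand_mode: str = "unstranded") -> list[float]:
    """Mean per-base signal over the strand-framed window at each anchor.

    ``strand_mode``: "anchor-strand" reads the anchor's own strand,
    "antisense-of-anchor" the opposite one, "unstranded" requires a plain
    per-chromosome track.  Windows are clipped at chromosome ends; a fully
    clipped window yields NaN.  The clip fraction is logged.
    """
    if rel_start >= rel_end:
        raise ValueError("rel_start must be < rel_end")
    if strand_mode not in ("anchor-strand", "antisense-of-anchor", "unstranded"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    out = []
    clipped = 0
    for chrom, pos, strand in anchors:
        if isinstance(track, StrandedTrack):
            read_strand = strand
            if strand_mode == "antisense-of-anchor":
                read_strand = "-" if strand == "+" else "+"
            a = track.array(chrom, read_strand)
        else:
            a = track[chrom]
        s, e = _window(pos, strand, rel_start, rel_end)
        cs, ce = max(s, 0), min(e, a.size)
        if ce <= cs:
            out.append(float("nan"))
            clipped += 1
            continue
        if (cs, ce) != (s, e):
            clipped += 1
        out.append(float(a[cs:ce].mean()))
    if clipped:
        logger.info("window_mean: %d/%d windows clipped", clipped, len(anchors))
    return out


@dataclass
class WindowStat:
    anchor: Anchor
    condition: str
    upstream_occupancy_mean: float
    downstream_initiation_mean: float


def window_stats(occupancy_track, signal_track: StrandedTrack, anchors: list[Anchor],
                 condition: str, upstream: int = 500, downstream: int = 200) -> list[WindowStat]:
    """Per-anchor occupancy (upstream, unstranded) and initiation (downstream,
    anchor strand) window means for one condition."""
    occ = window_mean(occupancy_track, anchors, -upstream, 0, "unstranded")
    ini = window_mean(signal_track, anchors, 0, downstream, "anchor-strand")
    return [
        WindowStat(a, condition, o, s) for a, o, s in zip(anchors, occ, ini)
    ]


def condition_summary(stats: list[WindowStat]) -> pd.DataFrame:
    """Per-condition mean and SEM of each window measure."""
    df = pd.DataFrame(
        {
            "condition": [s.condition for s in stats],
            "occupancy": [s.upstream_occupancy_mean for s in stats],
            "initiation": [s.downstream_initiation_mean for s in stats],
        }
    )
    g = df.groupby("condition", sort=False)
    out = g.agg(
        occupancy_mean=("occupancy", "mean"),
        occupancy_sem=("occupancy", "sem"),
        initiation_mean=("initiation", "mean"),
        initiation_sem=("initiation", "sem"),
        n=("occupancy", "count"),
    )
    return out


@dataclass
class CorrelationResult:
    spearman_r: float
    pearson_r: float
    slope: float
    intercept: float
    n: int


def occupancy_initiation_correlation(summaries: pd.DataFrame) -> CorrelationResult:
    """Rank and linear correlation of initiation vs occupancy across conditions."""
    x = summaries["occupancy_mean"].to_numpy(dtype=float)
    y = summaries["initiation_mean"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 condition points")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # degenerate: no association measurable
        lr = sps.linregress(x, y) if np.ptp(x) > 0 else None
        return CorrelationResult(0.0, 0.0, lr.slope if lr else 0.0,
                                 lr.intercept if lr else float(np.mean(y)), n)
    sr = sps.spearmanr(x, y).statistic
    pr = sps.pearsonr(x, y).statistic
    lr = sps.linregress(x, y)
    return CorrelationResult(float(sr), float(pr), float(lr.slope), float(lr.intercept), n)


def stratify_quartiles(values: dict[str, float] | pd.Series) -> pd.Series:
    """Empirical quartile labels Q1 (lowest) .. Q4, ties to the lower quartile."""
    s = pd.Series(values, dtype=float)
    cuts = np.quantile(s.to_numpy(), [0.25, 0.5, 0.75])
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    idx = np.searchsorted(cuts, s.to_numpy(), side="left")
    return pd.Series(labels[idx], index=s.index, name="quartile")


def partition_signal(track, genes: list[GeneModel]) -> tuple[float, float, dict[str, float]]:
    """Fraction of total signal inside vs outside annotated gene spans.

    Returns (genic fraction, intergenic fraction, raw sums); the raw sums of
    two tracks form the 2x2 table for a Fisher comparison.
    """
    if isinstance(track, StrandedTrack):
        arrays = {c: track.plus[c] + track.minus[c] for c in track.chroms()}
    else:
        arrays = track
    masks = {c: np.zeros(a.size, dtype=bool) for c, a in arrays.items()}
    for g in genes:
        masks[g.chrom][g.start:g.end] = True
    genic = sum(float(arrays[c][masks[c]].sum()) for c in arrays)
    total = sum(float(a.sum()) for a in arrays.values())
    if total <= 0:
        raise ValueError("track has no signal")
    genic_frac = genic / total
    return genic_frac, 1.0 - genic_frac, {"genic": genic, "intergenic": total - genic}
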