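"""End-to-end synthetic study: generate, analyze, and summarize.

Runs the full chain on the simulator's output — MNase fragments to dyad
calls, +1-anchored phasing metaplots across a severity series, occupancy and
antisense-initiation window statistics at the planted antisense TSSs, and
the cross-condition correlation — and reports recovery of the planted
structure.  Both the test suite and the reproduction script drive this one
entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nucleosome as nuc
from . import signal_quant as sq
from .synthetic import SimConfig, simulate_genome, simulate_mnase, simulate_proseq


@dataclass
class StudyResult:
    config: SimConfig
    deltas: list[float]
    dyad_recovery: float                 # planted dyads matched within +-10 bp (WT)
    false_call_fraction: float           # extra WT calls / planted count
    phasing_amplitudes: list[float]      # one per severity, +1-anchored profiles
    phasing_periods: list[int | None]
    summary: pd.DataFrame                # per-condition occupancy/initiation means
    correlation: sq.CorrelationResult
    mean_dyad_gc: dict[str, float]       # condition label -> mean dyad GC%
    n_planted_dyads: int = 0
    n_as_tss: int = 0
    extras: dict = field(default_factory=dict)


def run_synthetic_study(
    config: SimConfig | None = None,
    deltas: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
    n_fragments: int = 50_000,
    match_tolerance: int = 10,
    flank: int = 800,
) -> StudyResult:
    """Simulate one severity series and measure what the pipeline recovers."""
    config = config or SimConfig()
    genome, genes, truth = simulate_genome(config)
    guest_ids = {b for _, b in truth.nested_pairs}
    hosts = [g for g in genes if g.id not in guest_ids]
    as_anchors = [(c, p, s) for c, p, s, _ in truth.as_tss]

    amplitudes: list[float] = []
    periods: list[int | None] = []
    stats: list[sq.WindowStat] = []
    dyad_gc: dict[str, float] = {}
    recovery = float("nan")
    false_frac = float("nan")

    for delta in deltas:
        condition = "wt" if delta == 0 else "mutant"
        frags = simulate_mnase(genome, truth, condition, n_fragments, config,
                               occupancy_drop=None if delta == 0 else delta)
        density = nuc.midpoint_density(frags, genome)
        calls = nuc.call_dyads(density)

        if delta == min(deltas):
            pos = {c: calls.positions(c) for c in genome.seqs}
            hits = sum(
                pos[c].size > 0 and np.abs(pos[c] - p).min() <= match_tolerance
                for c, p in truth.dyads
            )
            recovery = hits / len(truth.dyads)
            false_frac = (len(calls) - hits) / len(truth.dyads)

        anchors, _skipped = nuc.plus_one_anchors(hosts, calls)
        profile = nuc.metaplot(density, anchors, flank, "library-mean-1")
        score = nuc.phasing_score(profile.mean_profile())
        amplitudes.append(score.amplitude)
        periods.append(score.period)

        gcs = nuc.dyad_gc(calls, genome)
        dyad_gc[f"delta_{delta:g}"] = float(np.nanmean(gcs))

        occupancy = nuc.fragment_coverage(frags, genome)
        track = simulate_proseq(genome, truth, genes, occupancy, condition, config)
        stats.extend(
            sq.window_stats(occupancy, track, as_anchors, f"delta_{delta:g}")
        )

    summary = sq.condition_summary(stats)
    corr = sq.occupancy_initiation_correlation(summary)
    return StudyResult(
        config=config,
        deltas=list(deltas),
        dyad_recovery=recovery,
        false_call_fraction=false_frac,
        phasing_amplitudes=amplitudes,
        phasing_periods=periods,
        summary=summary,
        correlation=corr,
        mean_dyad_gc=dyad_gc,
        n_planted_dyads=len(truth.dyads),
        n_as_tss=len(truth.as_tss),
    )
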