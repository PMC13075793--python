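"""Miniature-genome simulator with planted chromatin and antisense structure.

The generator emulates the statistical structure of a compact fungal genome
in which a CHD-family remodeler keeps gene-body nucleosome arrays phased:

* genes tile small chromosomes with intergenic gaps; a subset of genes carry
  one AT-rich intragenic "cryptic island" whose composition resembles a
  promoter (optionally with a TATA box on the antisense template strand);
* nucleosome dyads form +1-anchored arrays with ~150 bp spacing; in mutant
  conditions, dyads over cryptic islands lose occupancy and the remaining
  gene-body dyads blur (higher positional jitter), in proportion to the
  condition severity;
* nascent-transcription signal has a sense pausing peak downstream of each
  TSS, and antisense initiation at each planted antisense TSS whose rate
  grows linearly with the nucleosome depletion of the 500 bp upstream of it;
* sense/antisense expression counts are negative binomial, with a planted
  antisense fold change at island-bearing genes in the mutant.

Every output is deterministic given the config seed; random streams are
keyed per data layer so e.g. changing the fragment count does not perturb
the genome sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeSequence, FragmentSet, StrandedTrack, reverse_complement

# stream keys, mixed with the user seed per data layer
_GENOME_STREAM = 1
_MNASE_STREAM = 2
_PROSEQ_STREAM = 3
_COUNTS_STREAM = 4

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

TATA_CONSENSUS = "TATAWAWR"


@dataclass
class SimConfig:
    """Study conditions for the simulated genome.

    Lengths are bp, rates are per-event; ``occupancy_drop`` is the fraction
    of occupancy lost at cryptic islands in the mutant, and
    ``antisense_coupling`` the expected number of antisense initiation
    events per antisense TSS at full upstream nucleosome depletion.
    """

    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 60
    fraction_nested_convergent: float = 0.10
    fraction_with_island: float = 1 / 3
    nucleosome_spacing: int = 150
    jitter_sd_wt: float = 10.0
    jitter_sd_mut: float = 25.0
    jitter_walk_cap: int = 4
    occupancy_drop: float = 0.6
    island_length: int = 500
    island_at_fraction: float = 0.70
    background_gc: float = 0.36
    tata_prob: float = 0.2
    sense_pause_height: float = 3.0
    sense_body_rate: float = 0.2
    antisense_coupling: float = 40.0
    antisense_read_length: int = 50
    nb_dispersion: float = 0.05
    count_mean: float = 100.0
    antisense_fold_change: float = 4.0
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    fragment_length_bounds: tuple[int, int] = (120, 180)
    gene_length_range: tuple[int, int] = (2000, 4000)
    gap_range: tuple[int, int] = (200, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_nested_convergent", "fraction_with_island",
                     "occupancy_drop", "island_at_fraction", "background_gc",
                     "tata_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nucleosome_spacing <= 0:
            raise ValueError("nucleosome_spacing must be > 0")
        if self.jitter_sd_wt < 0 or self.jitter_sd_mut < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted structure, carried so downstream recovery can be asserted."""

    dyads: list[tuple[str, int]]
    island_dyad_idx: set[int]
    islands: list[tuple[str, int, int, str]]            # chrom, start, end, gene id
    as_tss: list[tuple[str, int, str, str]]             # chrom, pos, strand, gene id
    tata_genomic_centers: list[tuple[str, int]]
    nested_pairs: list[tuple[str, str]]                 # (host id, guest id)
    antisense_fc: dict[str, float] = field(default_factory=dict)
    # position of each dyad within its gene-body array (0 = the +1 nucleosome)
    dyad_k: list[int] = field(default_factory=list)


def _rng(config: SimConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _sample_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus)


def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Build the genome sequence, gene annotation, and planted ground truth."""
    rng = _rng(config, _GENOME_STREAM)
    n_guests = round(config.fraction_nested_convergent * config.n_genes)
    n_hosts = config.n_genes - n_guests
    per_chrom = np.full(config.n_chroms, n_hosts // config.n_chroms)
    per_chrom[: n_hosts % config.n_chroms] += 1

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {c: list(_random_seq(rng, config.chrom_length, config.background_gc))
            for c in chrom_names}

    genes: list[GeneModel] = []
    gidx = 0
    for ci, chrom in enumerate(chrom_names):
        pos = int(rng.integers(*config.gap_range)) + 500
        for _ in range(per_chrom[ci]):
            glen = int(rng.integers(*config.gene_length_range))
            if pos + glen + 500 > config.chrom_length:
                raise ValueError(
                    f"genome too small: cannot place {config.n_genes} genes of "
                    f"{config.gene_length_range} bp on {config.n_chroms} x "
                    f"{config.chrom_length} bp chromosomes"
                )
            gidx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gidx:04d}", chrom, pos, pos + glen, strand))
            pos += glen + int(rng.integers(*config.gap_range))

    # cryptic islands: AT-rich window mid-gene in a subset of (host) genes
    n_islands = round(config.fraction_with_island * config.n_genes)
    eligible = [g for g in genes if g.length >= config.island_length + 800]
    island_genes = list(rng.choice(eligible, size=min(n_islands, len(eligible)),
                                   replace=False))
    islands, as_tss, tata_centers = [], [], []
    for g in island_genes:
        mid = (g.start + g.end) // 2
        s = mid - config.island_length // 2
        e = s + config.island_length
        islands.append((g.chrom, s, e, g.id))
        seq = list(_random_seq(rng, config.island_length, 1 - config.island_at_fraction))
        seqs[g.chrom][s:e] = seq
        anti = "-" if g.strand == "+" else "+"
        # the 500 bp upstream of the antisense TSS is (essentially) the island
        tss = s if anti == "-" else e
        as_tss.append((g.chrom, tss, anti, g.id))
        if rng.random() < config.tata_prob:
            word = _sample_iupac(rng, TATA_CONSENSUS)
            W = len(word)
            # plant so the match center sits 30 bp upstream of the As-TSS in
            # the promoter frame
            offset = (500 - 30) - W // 2            # offset within the promoter
            if anti == "-":
                gstart = tss + 500 - offset - W + 1
                seqs[g.chrom][gstart:gstart + W] = list(reverse_complement(word))
                tata_centers.append((g.chrom, tss + 30))
            else:
                gstart = tss - 500 + offset
                seqs[g.chrom][gstart:gstart + W] = list(word)
                tata_centers.append((g.chrom, tss - 30))

    # convergently nested guests: opposite strand, strictly inside a host
    island_ids = {g.id for g in island_genes}
    host_pool = [g for g in genes if g.id not in island_ids and g.length >= 1200]
    hosts = list(rng.choice(host_pool, size=min(n_guests, len(host_pool)), replace=False))
    nested_pairs = []
    guests = []
    for host in hosts:
        gidx += 1
        glen = int(rng.integers(400, 801))
        margin = 100
        gstart = int(rng.integers(host.start + margin, host.end - margin - glen))
        guest = GeneModel(
            f"g{gidx:04d}", host.chrom, gstart, gstart + glen,
            "-" if host.strand == "+" else "+",
        )
        guests.append(guest)
        nested_pairs.append((host.id, guest.id))
    genes = sorted(genes + guests, key=lambda g: (g.chrom, g.start))

    # +1-anchored dyad arrays along each (host) gene body
    dyads: list[tuple[str, int]] = []
    dyad_k: list[int] = []
    island_dyad_idx: set[int] = set()
    island_by_gene = {gid: (s, e) for c, s, e, gid in islands}
    guest_ids = {g.id for g in guests}
    L = config.nucleosome_spacing
    for g in genes:
        if g.id in guest_ids:
            continue                                # hosts carry the array
        n_nuc = (g.length - L // 2 - 75) // L + 1
        for k in range(max(n_nuc, 0)):
            if g.strand == "+":
                pos = g.start + L // 2 + k * L
            else:
                pos = g.end - 1 - L // 2 - k * L
            idx = len(dyads)
            dyads.append((g.chrom, pos))
            dyad_k.append(k)
            isl = island_by_gene.get(g.id)
            if isl is not None and isl[0] <= pos < isl[1]:
                island_dyad_idx.add(idx)

    truth = GroundTruth(
        dyads=dyads,
        island_dyad_idx=island_dyad_idx,
        islands=islands,
        as_tss=as_tss,
        tata_genomic_centers=tata_centers,
        nested_pairs=nested_pairs,
        antisense_fc={
            g.id: (config.antisense_fold_change if g.id in island_ids else 1.0)
            for g in genes
        },
        dyad_k=dyad_k,
    )
    genome = GenomeSequence({c: "".join(s) for c, s in seqs.items()})
    return genome, genes, truth


def simulate_mnase(
    genome: GenomeSequence,
    truth: GroundTruth,
    condition: str,
    n_fragments: int,
    config: SimConfig,
    occupancy_drop: float | None = None,
) -> FragmentSet:
    """Sample MNase fragments around the planted dyads.

    ``condition`` is ``"wt"`` or ``"mutant"``.  Positional jitter is a
    random walk along the array: the +1/+2 nucleosomes keep the anchor SD,
    and dyad k (>= 2) has SD sigma * sqrt(min(k - 1, cap)), so phasing
    decays with distance from the +1 barrier but saturates (re-phasing by
    flanking barriers).  In the mutant, island dyads lose
    occupancy with probability ``occupancy_drop`` (default from the config)
    and sigma is interpolated from ``jitter_sd_wt`` toward ``jitter_sd_mut``
    in proportion to the drop, so a severity series delta = 0 reproduces
    the WT exactly.
    """
    if condition not in ("wt", "mutant"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    delta = 0.0
    if condition == "mutant":
        delta = config.occupancy_drop if occupancy_drop is None else occupancy_drop
    rng = _rng(config, _MNASE_STREAM, 0 if condition == "wt" else 1,
               int(round(delta * 1000)))

    chroms = np.array([c for c, _ in truth.dyads])
    positions = np.array([p for _, p in truth.dyads], dtype=float)
    ks = np.array(truth.dyad_k, dtype=float)
    weights = np.ones(len(positions))
    sigma = config.jitter_sd_wt + delta * (config.jitter_sd_mut - config.jitter_sd_wt)
    if delta > 0 and truth.island_dyad_idx:
        isl = np.fromiter(truth.island_dyad_idx, dtype=int, count=len(truth.island_dyad_idx))
        weights[isl] = 1.0 - delta
    weights = weights / weights.sum()
    # random-walk spacing jitter: tight +1/+2, blur grows along the array but
    # saturates after jitter_walk_cap linkers (re-phasing by flanking barriers)
    steps = np.clip(ks - 1, 0, config.jitter_walk_cap)
    sds = np.where(ks <= 1, config.jitter_sd_wt, sigma * np.sqrt(steps))

    picks = rng.choice(len(positions), size=n_fragments, p=weights)
    mids = positions[picks] + rng.normal(0.0, 1.0, size=n_fragments) * sds[picks]
    lo, hi = config.fragment_length_bounds
    lengths = np.clip(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_fragments),
        lo, hi,
    ).round().astype(int)
    mids = mids.round().astype(int)

    records = []
    for chrom, mid, ln in zip(chroms[picks], mids, lengths):
        start = int(mid) - ln // 2
        end = start + ln
        L = genome.length(chrom)
        start = max(0, min(start, L - ln))
        records.append((chrom, start, start + ln))
    records.sort()
    return FragmentSet(records)


def occupancy_reference(coverage: dict[str, np.ndarray], truth: GroundTruth) -> float:
    """Full-occupancy coverage scale: median coverage at non-island dyads."""
    vals = [
        coverage[c][p]
        for i, (c, p) in enumerate(truth.dyads)
        if i not in truth.island_dyad_idx
    ]
    ref = float(np.median(vals))
    if ref <= 0:
        raise ValueError("coverage has no signal at planted dyads")
    return ref


def simulate_proseq(
    genome: GenomeSequence,
    truth: GroundTruth,
    genes: list[GeneModel],
    occupancy: dict[str, np.ndarray],
    condition: str,
    config: SimConfig,
) -> StrandedTrack:
    """Nascent-transcription signal coupled to nucleosome occupancy.

    Sense strand: per-base Poisson signal over gene bodies with a pausing
    bump in the first 200 bp downstream of each TSS.  Antisense strand:
    Poisson initiation at each planted antisense TSS with rate
    ``antisense_coupling x (1 - mean upstream occupancy)``, each event laid
    down as a fixed-length read extending downstream.
    """
    if condition not in ("wt", "mutant"):
        raise ValueError(f"unknown condition {condition!r}")
    for c in genome.seqs:
        if c not in occupancy or len(occupancy[c]) != genome.length(c):
            raise ValueError(f"occupancy track length mismatch on {c}")
    rng = _rng(config, _PROSEQ_STREAM, 0 if condition == "wt" else 1)

    plus = {c: np.zeros(genome.length(c)) for c in genome.seqs}
    minus = {c: np.zeros(genome.length(c)) for c in genome.seqs}

    for g in genes:
        rate = np.full(g.length, config.sense_body_rate)
        if g.strand == "+":
            rate[: min(200, g.length)] += config.sense_pause_height
            plus[g.chrom][g.start:g.end] += rng.poisson(rate)
        else:
            rate[max(g.length - 200, 0):] += config.sense_pause_height
            minus[g.chrom][g.start:g.end] += rng.poisson(rate)

    ref = occupancy_reference(occupancy, truth)
    rl = config.antisense_read_length
    for chrom, pos, strand, _gid in truth.as_tss:
        if strand == "-":
            up = occupancy[chrom][pos + 1: pos + 501]
        else:
            up = occupancy[chrom][max(pos - 500, 0): pos]
        exposure = max(0.0, 1.0 - float(np.mean(up)) / ref)
        n_events = rng.poisson(config.antisense_coupling * exposure)
        if n_events == 0:
            continue
        L = genome.length(chrom)
        if strand == "+":
            s, e = pos, min(pos + rl, L)
            plus[chrom][s:e] += n_events
        else:
            s, e = max(pos - rl + 1, 0), pos + 1
            minus[chrom][s:e] += n_events
    return StrandedTrack(plus=plus, minus=minus)


def simulate_tata_promoters(
    n_promoters: int,
    planting_prob: float,
    seed: int,
    length: int = 500,
    carrier_gc: float = 0.80,
    center: int = -30,
    center_jitter: int = 3,
) -> tuple[list[str], list[bool], list[int]]:
    """Random promoter sequences with a TATA box planted in a known fraction.

    Each promoter is an i.i.d. carrier sequence (GC-rich by default, so that
    chance TATA-like matches are rare); with ``planting_prob`` a TATAWAWR
    instance is written with its match center at ``center`` +- jitter
    relative to the TSS (position 0 is just right of the sequence).

    Returns (sequences, planted flags, planted centers; -1 where unplanted).
    """
    if not 0.0 <= planting_prob <= 1.0:
        raise ValueError("planting_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    W = len(TATA_CONSENSUS)
    seqs, flags, centers = [], [], []
    for _ in range(n_promoters):
        seq = list(_random_seq(rng, length, carrier_gc))
        planted = bool(rng.random() < planting_prob)
        c = -1
        if planted:
            c = center + int(rng.integers(-center_jitter, center_jitter + 1))
            word = _sample_iupac(rng, TATA_CONSENSUS)
            start = (length + c) - W // 2      # promoter index of match start
            seq[start:start + W] = list(word)
        seqs.append("".join(seq))
        flags.append(planted)
        centers.append(c)
    return seqs, flags, centers


@dataclass
class CountMatrix:
    """Feature x sample integer counts with orientation and condition labels."""

    counts: pd.DataFrame                   # features x samples
    feature_meta: pd.DataFrame             # columns: gene_id, orientation
    conditions: pd.Series                  # per-sample condition label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not list(self.counts.index) == list(self.feature_meta.index):
            raise ValueError("feature metadata does not match count rows")
        if not list(self.counts.columns) == list(self.conditions.index):
            raise ValueError("condition labels do not match count columns")


def simulate_counts(truth: GroundTruth, n_samples_per_condition: int,
                    config: SimConfig) -> CountMatrix:
    """Negative-binomial sense/antisense expression counts.

    Sense features keep the same mean in both conditions; antisense features
    of island-bearing genes change by the planted fold change in the mutant.
    """
    if n_samples_per_condition < 2:
        raise ValueError("need >= 2 samples per condition")
    rng = _rng(config, _COUNTS_STREAM)
    gene_ids = sorted(truth.antisense_fc)
    features, means_wt, means_mut = [], [], []
    for gid in gene_ids:
        features.append((f"{gid}:sense", gid, "sense"))
        means_wt.append(config.count_mean)
        means_mut.append(config.count_mean)
        features.append((f"{gid}:antisense", gid, "antisense"))
        base = config.count_mean / 4.0       # antisense baseline below sense
        means_wt.append(base)
        means_mut.append(base * truth.antisense_fc[gid])
    means_wt = np.array(means_wt)
    means_mut = np.array(means_mut)

    alpha = config.nb_dispersion
    n_param = 1.0 / alpha

    def draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        mu_mat = np.tile(mu[:, None], (1, n_samples))
        if alpha < 1e-8:
            return rng.poisson(mu_mat)
        p = n_param / (n_param + mu_mat)
        return rng.negative_binomial(n_param, p)

    wt = draw(means_wt, n_samples_per_condition)
    mut = draw(means_mut, n_samples_per_condition)
    sample_ids = [f"wt_{i+1}" for i in range(n_samples_per_condition)] + [
        f"mutant_{i+1}" for i in range(n_samples_per_condition)
    ]
    counts = pd.DataFrame(
        np.hstack([wt, mut]),
        index=[f[0] for f in features],
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        {"gene_id": [f[1] for f in features], "orientation": [f[2] for f in features]},
        index=counts.index,
    )
    conditions = pd.Series(
        ["wt"] * n_samples_per_condition + ["mutant"] * n_samples_per_condition,
        index=sample_ids,
        name="condition",
    )
    return CountMatrix(counts=counts, feature_meta=meta, conditions=conditions)
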