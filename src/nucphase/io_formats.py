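"""Readers and writers for the standard genomics formats used by the pipeline.

All coordinates are normalized onto one internal convention at the boundary:
0-based, half-open intervals on named chromosomes.  GFF3 (1-based, closed) is
converted on load and on write; BED and bedGraph already match.

Strands are the two characters ``+`` and ``-``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from urllib.parse import unquote

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GFF3ParseError(ValueError):
    """Malformed GFF3 input, with the offending line number."""


@dataclass
class GenomeSequence:
    """Per-chromosome uppercase nucleotide strings over the alphabet ACGTN."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        norm = {}
        for name, s in self.seqs.items():
            s = s.upper()
            extra = set(s) - allowed
            if extra:
                raise ValueError(f"chromosome {name}: non-ACGTN characters {sorted(extra)}")
            if len(s) == 0:
                raise ValueError(f"chromosome {name} has zero length")
            norm[name] = s
        self.seqs = norm

    def __len__(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); bounds are checked, not clipped."""
        L = self.length(chrom)
        if not (0 <= start <= end <= L):
            raise ValueError(f"window [{start}, {end}) outside {chrom} [0, {L})")
        return self.seqs[chrom][start:end]


@dataclass
class GeneModel:
    """A stranded annotated gene: span plus ordered disjoint exon blocks."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = self.start - 1
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end or s < prev_end:
                raise ValueError(f"gene {self.id}: bad exon blocks {self.exons}")
            prev_end = e

    @property
    def tss(self) -> int:
        """Strand-aware transcription start position (a single base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A (long-read) transcript: exon blocks plus a strand-aware 5' end."""

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exon blocks")
        self.exons = sorted(self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"transcript {self.id}: empty exon ({s},{e})")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Internal exon-junction chain (intron intervals)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class StrandedTrack:
    """Dense per-base, per-strand non-negative signal (PRO-seq style)."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for arrs in (self.plus, self.minus):
            for chrom, a in arrs.items():
                a = np.asarray(a, dtype=float)
                if not np.all(np.isfinite(a)) or np.any(a < 0):
                    raise ValueError(f"{chrom}: track values must be finite and >= 0")
                arrs[chrom] = a
        if set(self.plus) != set(self.minus):
            raise ValueError("plus/minus chromosome sets differ")

    def chroms(self) -> list[str]:
        return list(self.plus)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        return self.plus[chrom] if strand == "+" else self.minus[chrom]

    def total(self) -> float:
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )


@dataclass
class FragmentSet:
    """MNase paired-end fragments as plain (chrom, start, end) intervals."""

    records: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, s, e in self.records:
            if e <= s:
                raise ValueError(f"fragment {chrom}:{s}-{e} has end <= start")

    def __len__(self) -> int:
        return len(self.records)

    def midpoints(self) -> list[tuple[str, int]]:
        return [(c, (s + e) // 2) for c, s, e in self.records]


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[unquote(k)] = unquote(v)
    return out


def _iter_gff3_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError as exc:
                raise GFF3ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GFF3ParseError(f"{path}:{lineno}: bad coordinate pair {start},{end}")
            yield lineno, fields, start, end


def load_annotation(path, biotype_filter: str | None = None) -> list[GeneModel]:
    """Load ``gene`` features from an Ensembl-dialect GFF3 file.

    1-based closed GFF3 coordinates become 0-based half-open.  Exon blocks of
    any child transcripts are merged per gene; genes without annotated exons
    span a single block.  Records with an unknown strand symbol are dropped
    with a warning.
    """
    genes: dict[str, GeneModel] = {}
    # parent id -> owning gene id, so exons can be attached through mRNA rows
    parent_gene: dict[str, str] = {}
    exon_blocks: dict[str, list[tuple[int, int]]] = {}

    for lineno, fields, start1, end1 in _iter_gff3_lines(path):
        chrom, _source, ftype, _s, _e, _score, strand, _frame, attr_text = fields
        attrs = _parse_attributes(attr_text)
        start, end = start1 - 1, end1
        if ftype == "gene":
            if strand not in STRANDS:
                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record dropped")
                continue
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise GFF3ParseError(f"{path}:{lineno}: gene feature without ID")
            gid = gid.removeprefix("gene:")
            biotype = attrs.get("biotype") or attrs.get("gene_biotype") or "protein_coding"
            genes[gid] = GeneModel(gid, chrom, start, end, strand, biotype, exons=[])
            parent_gene[gid] = gid
        elif ftype == "exon":
            parent = attrs.get("Parent", "").removeprefix("transcript:")
            gid = parent_gene.get(parent)
            if gid is not None:
                exon_blocks.setdefault(gid, []).append((start, end))
        else:
            parent = attrs.get("Parent", "").removeprefix("gene:")
            ident = (attrs.get("ID") or "").removeprefix("transcript:")
            if parent in parent_gene and ident:
                parent_gene[ident] = parent_gene[parent]

    out = []
    for gid, g in genes.items():
        blocks = exon_blocks.get(gid)
        if blocks:
            g.exons = _merge_blocks(blocks)
            g.__post_init__()
        if biotype_filter is None or g.biotype == biotype_filter:
            out.append(g)
    logger.info("loaded %d gene models from %s", len(out), path)
    return out


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks = sorted(blocks)
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def write_annotation(genes: list[GeneModel], path, source: str = "nucphase") -> None:
    """Write gene (and exon) features back out as GFF3, 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id};biotype={g.biotype}\n"
            )
            if g.exons != [(g.start, g.end)]:
                for i, (s, e) in enumerate(g.exons, start=1):
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.id}.exon{i};Parent={g.id}\n"
                    )


def load_transcripts_gff3(path) -> list[TranscriptModel]:
    """Load transcript models (mRNA/transcript features + exon children)."""
    tx: dict[str, dict] = {}
    for lineno, fields, start1, end1 in _iter_gff3_lines(path):
        chrom, _src, ftype, _s, _e, _score, strand, _frame, attr_text = fields
        attrs = _parse_attributes(attr_text)
        if ftype in ("mRNA", "transcript"):
            if strand not in STRANDS:
                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record dropped")
                continue
            tid = (attrs.get("ID") or "").removeprefix("transcript:")
            if not tid:
                raise GFF3ParseError(f"{path}:{lineno}: transcript without ID")
            tx[tid] = {"chrom": chrom, "strand": strand, "exons": []}
        elif ftype == "exon":
            parent = attrs.get("Parent", "").removeprefix("transcript:")
            if parent in tx:
                tx[parent]["exons"].append((start1 - 1, end1))
    return [
        TranscriptModel(tid, d["chrom"], d["strand"], d["exons"])
        for tid, d in tx.items()
        if d["exons"]
    ]


# ---------------------------------------------------------------------------
# BED / BED12


def load_transcripts_bed12(path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in STRANDS:
                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record dropped")
                continue
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def load_fragments(path) -> FragmentSet:
    """BED3 intervals; records with end <= start are dropped with a warning."""
    recs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                warnings.warn(f"{path}:{lineno}: end <= start, record dropped")
                continue
            recs.append((chrom, start, end))
    recs.sort()
    return FragmentSet(recs)


def write_bed(records, path) -> None:
    """Write (chrom, start, end[, name, score, strand]) tuples, sorted."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: (r[0], r[1], r[2])):
            fh.write("\t".join(str(x) for x in rec) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def _load_bedgraph_array(path, genome: GenomeSequence) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(genome.length(c)) for c in genome.seqs}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in arrays:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < 0 or end > genome.length(chrom) or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} outside "
                    f"[0, {genome.length(chrom)})"
                )
            # overlapping intervals are summed, by contract
            arrays[chrom][start:end] += value
    return arrays


def load_stranded_track(plus_path, minus_path, genome: GenomeSequence) -> StrandedTrack:
    return StrandedTrack(
        plus=_load_bedgraph_array(plus_path, genome),
        minus=_load_bedgraph_array(minus_path, genome),
    )


def load_unstranded_track(path, genome: GenomeSequence) -> dict[str, np.ndarray]:
    return _load_bedgraph_array(path, genome)


def write_bedgraph(arrays: dict[str, np.ndarray], path) -> None:
    """Write dense arrays as run-length-merged bedGraph; zero runs omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            a = np.asarray(arrays[chrom], dtype=float)
            if a.size == 0:
                continue
            change = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [a.size]])
            for s, e in zip(starts, ends):
                v = a[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
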