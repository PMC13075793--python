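"""Transcript-model collapsing and antisense classification.

Long-read transcript models are first collapsed (transcripts with identical
internal exon-junction chains and sufficiently close 5'/3' ends merge into a
single representative), then classified against a reference annotation: a
model is an antisense call when at least one of its exons overlaps, by at
least one base, an exon of a reference gene on the opposite strand.
Antisense TSS anchors are the strand-aware 5' ends of those calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

ANTISENSE_EXONIC = "antisense_exonic"
OTHER = "other"


@dataclass
class CollapseParams:
    end_tolerance_5prime: int = 100
    end_tolerance_3prime: int = 100
    require_same_exon_count: bool = True

    def __post_init__(self) -> None:
        if self.end_tolerance_5prime < 0 or self.end_tolerance_3prime < 0:
            raise ValueError("end tolerances must be >= 0")


@dataclass
class AntisenseCall:
    transcript_id: str
    gene_ids: list[str]
    label: str
    as_tss: tuple[str, int, str] = field(default=None)  # chrom, pos, strand


def _ends_5p_3p(t: TranscriptModel) -> tuple[int, int]:
    if t.strand == "+":
        return t.start, t.end
    return t.end, t.start


def _mergeable(a: TranscriptModel, b: TranscriptModel, params: CollapseParams) -> bool:
    if params.require_same_exon_count and len(a.exons) != len(b.exons):
        return False
    a5, a3 = _ends_5p_3p(a)
    b5, b3 = _ends_5p_3p(b)
    if abs(a5 - b5) > params.end_tolerance_5prime:
        return False
    if abs(a3 - b3) > params.end_tolerance_3prime:
        return False
    if len(a.exons) > 1 or len(b.exons) > 1:
        return a.junctions == b.junctions
    # single-exon models must additionally overlap
    return a.start < b.end and b.start < a.end


def collapse_transcripts(models: list[TranscriptModel],
                         params: CollapseParams | None = None) -> list[TranscriptModel]:
    """Merge redundant transcript models (single-linkage transitive closure).

    The representative of each merge group is the longest-span member, ties
    broken toward the leftmost.  Models on different chromosomes or strands
    never merge.
    """
    params = params or CollapseParams()
    groups: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.chrom, m.strand), []).append(m)

    out: list[TranscriptModel] = []
    for _, ms in sorted(groups.items()):
        n = len(ms)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ms_sorted = sorted(ms, key=lambda t: t.start)
        for i in range(n):
            for j in range(i + 1, n):
                # candidates further right than every tolerance cannot merge
                if ms_sorted[j].start - ms_sorted[i].end > max(
                    params.end_tolerance_5prime, params.end_tolerance_3prime
                ):
                    break
                if _mergeable(ms_sorted[i], ms_sorted[j], params):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[TranscriptModel]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(ms_sorted[i])
        for members in clusters.values():
            rep = min(members, key=lambda t: (-(t.end - t.start), t.start))
            out.append(rep)
    out.sort(key=lambda t: (t.chrom, t.start, t.id))
    return out


def _exon_trees(reference: list[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in reference:
        tree = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for s, e in g.exons:
            tree[s:e] = g.id
    return trees


def classify_antisense(models: list[TranscriptModel],
                       reference: list[GeneModel]) -> list[AntisenseCall]:
    """Label each transcript by exonic overlap with opposite-strand genes.

    Same-strand exonic overlap takes precedence: a model touching exons of
    genes on both strands is not called antisense (logged).  Intron-only
    opposite-strand overlap is not antisense.
    """
    trees = _exon_trees(reference)
    calls = []
    both_strand = 0
    for m in models:
        opp = "-" if m.strand == "+" else "+"
        same_tree = trees.get((m.chrom, m.strand))
        opp_tree = trees.get((m.chrom, opp))
        same_hit = same_tree is not None and any(
            same_tree.overlap(s, e) for s, e in m.exons
        )
        gene_ids: set[str] = set()
        if opp_tree is not None:
            for s, e in m.exons:
                gene_ids.update(iv.data for iv in opp_tree.overlap(s, e))
        if gene_ids and not same_hit:
            calls.append(AntisenseCall(
                transcript_id=m.id,
                gene_ids=sorted(gene_ids),
                label=ANTISENSE_EXONIC,
                as_tss=(m.chrom, m.five_prime_end, m.strand),
            ))
        else:
            if gene_ids and same_hit:
                both_strand += 1
            calls.append(AntisenseCall(
                transcript_id=m.id,
                gene_ids=sorted(gene_ids),
                label=OTHER,
                as_tss=(m.chrom, m.five_prime_end, m.strand),
            ))
    if both_strand:
        logger.info("classify_antisense: %d models overlapped exons on both "
                    "strands and were kept same-strand (not antisense)", both_strand)
    return calls


def derive_as_tss(calls: list[AntisenseCall]) -> list[tuple[str, int, str]]:
    """Deduplicated antisense TSS anchors from the antisense calls."""
    seen = set()
    anchors = []
    for c in calls:
        if c.label != ANTISENSE_EXONIC:
            continue
        if c.as_tss not in seen:
            seen.add(c.as_tss)
            anchors.append(c.as_tss)
    anchors.sort()
    return anchors
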