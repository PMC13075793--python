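"""Convergently nested gene cataloguing.

A convergently nested pair is a gene entirely embedded, on the opposite
strand, within a longer host gene.  When a guest fits several hosts the
smallest containing host is its primary pair; every containing host is kept
in a secondary field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel


@dataclass
class NestedPair:
    host_id: str
    guest_id: str
    chrom: str
    guest_start: int
    guest_end: int
    margin: int                      # min distance from guest ends to host ends
    all_host_ids: list[str] = field(default_factory=list)


def find_nested_convergent(genes: list[GeneModel],
                           use_cds_span: bool = False) -> list[NestedPair]:
    """Catalog guests fully inside an opposite-strand host gene.

    Containment is over gene-feature spans by default (``use_cds_span``
    switches to the span of the exon blocks).  One primary pair per guest;
    output sorted by chromosome then guest start.
    """

    def span(g: GeneModel) -> tuple[int, int]:
        if use_cds_span:
            return g.exons[0][0], g.exons[-1][1]
        return g.start, g.end

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = span(g)
        trees.setdefault(g.chrom, IntervalTree())[s:e] = g

    pairs = []
    for guest in genes:
        gs, ge = span(guest)
        hosts = [
            iv.data for iv in trees[guest.chrom].overlap(gs, ge)
            if iv.data.id != guest.id
            and iv.data.strand != guest.strand
            and span(iv.data)[0] <= gs
            and span(iv.data)[1] >= ge
        ]
        if not hosts:
            continue
        hosts.sort(key=lambda h: (span(h)[1] - span(h)[0], h.start, h.id))
        primary = hosts[0]
        hs, he = span(primary)
        pairs.append(NestedPair(
            host_id=primary.id,
            guest_id=guest.id,
            chrom=guest.chrom,
            guest_start=gs,
            guest_end=ge,
            margin=min(gs - hs, he - ge),
            all_host_ids=[h.id for h in hosts],
        ))
    pairs.sort(key=lambda p: (p.chrom, p.guest_start, p.guest_id))
    return pairs


def pair_with_sets(pairs: list[NestedPair], gene_sets: dict[str, set[str]],
                   universe: set[str]) -> pd.DataFrame:
    """Per-gene boolean membership matrix over the universe.

    Columns: ``nested_guest`` plus one per named set, for UpSet-style
    intersection counting.  Ids outside the universe raise a warning and are
    excluded.
    """
    guests = {p.guest_id for p in pairs}
    stray = guests - universe
    for name, s in gene_sets.items():
        stray |= s - universe
    if stray:
        warnings.warn(f"{len(stray)} gene ids outside the universe were excluded")
    cols = {"nested_guest": guests & universe}
    cols.update({name: s & universe for name, s in gene_sets.items()})
    index = sorted(universe)
    return pd.DataFrame(
        {name: [g in members for g in index] for name, members in cols.items()},
        index=index,
    )


def intersection_counts(membership: pd.DataFrame) -> pd.Series:
    """Counts of every non-empty combination of set memberships."""
    key = membership.apply(lambda row: tuple(membership.columns[row.values]), axis=1)
    key = key[key.apply(len) > 0]
    return key.value_counts()
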