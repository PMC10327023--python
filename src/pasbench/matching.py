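"""Windowed GT-PD matching and the event-specific split/merge rules.

A prediction matches a ground-truth site when it lies within ``n``
nucleotides of it on the same chromosome (and, by default, the same
strand): the GT coordinate is extended by ``n`` in both directions and any
PD site inside the closed interval [gt - n, gt + n] pairs with it.  All
qualifying pairs are kept (many-to-many), and each metric suite applies its
own post-processing to the table.
"""

from __future__ import annotations

from typing import Mapping

from intervaltree import IntervalTree

from pasbench.types import (
    GtAssignedExpression,
    MatchPair,
    MatchTable,
    PasSet,
)

WINDOW_PRESETS = (10, 25, 50, 100)


def match_sites(
    gt: PasSet, pd: PasSet, window_n: int, ignore_strand: bool = False
) -> MatchTable:
    """All (PD, GT) pairs with |pd_pos - gt_pos| <= window_n.

    Uses an interval index over the extended GT windows; strand-aware by
    default (``ignore_strand=True`` restores the permissive intersection
    behaviour of plain interval tools).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in gt:
        key = (g.chrom, "." if ignore_strand else g.strand)
        tree = trees.setdefault(key, IntervalTree())
        # closed window [pos-n, pos+n] as half-open [pos-n, pos+n+1)
        tree.addi(g.pos - window_n, g.pos + window_n + 1, (g.site_id, g.pos))
    pairs: list[MatchPair] = []
    for p in pd:
        key = (p.chrom, "." if ignore_strand else p.strand)
        tree = trees.get(key)
        if tree is None:
            continue
        for iv in tree.at(p.pos):
            gt_id, gt_pos = iv.data
            pairs.append(MatchPair(p.site_id, gt_id, abs(p.pos - gt_pos)))
    return MatchTable(window_n, pairs)


def brute_force_match(
    gt: PasSet, pd: PasSet, window_n: int, ignore_strand: bool = False
) -> MatchTable:
    """O(|GT| x |PD|) all-pairs scan of the same predicate; the reference
    oracle for :func:`match_sites`."""
    pairs = [
        MatchPair(p.site_id, g.site_id, abs(p.pos - g.pos))
        for p in pd
        for g in gt
        if p.chrom == g.chrom
        and (ignore_strand or p.strand == g.strand)
        and abs(p.pos - g.pos) <= window_n
    ]
    return MatchTable(window_n, pairs)


def split_merge_expression(
    match_table: MatchTable, gt: PasSet, pd: PasSet
) -> GtAssignedExpression:
    """Assign predicted expression to GT sites for absolute quantification.

    A PD site matching several GT sites splits its score into shares
    inversely proportional to distance, with a pseudo-distance of d + 1 so
    that d = 0 is defined: share_i = score * (1/(d_i+1)) / sum_j 1/(d_j+1).
    Several PD sites matching one GT site merge by summing their shares.
    Total predicted mass is conserved exactly between the per-GT aggregates
    and the unmatched remainder.
    """
    by_pd = match_table.by_pd()
    assigned: dict[str, float] = {g.site_id: 0.0 for g in gt if g.site_id in match_table.matched_gt_ids()}
    unmatched = 0.0
    for p in pd:
        matches = by_pd.get(p.site_id)
        if not matches:
            unmatched += p.score
            continue
        weights = [1.0 / (m.distance + 1) for m in matches]
        wsum = sum(weights)
        for m, w in zip(matches, weights):
            assigned[m.gt_id] += p.score * w / wsum
    return GtAssignedExpression(assigned=assigned, unmatched_pd_score=unmatched)


def select_best_pd(
    matches: MatchTable,
    gt_values: Mapping[str, float],
    pd_values: Mapping[str, float],
    pd_order: Mapping[str, int] | None = None,
) -> MatchTable:
    """Per GT site keep only the pair whose PD value is closest to the GT
    value (best-PD mode for relative quantification).

    Ties break on smaller distance, then on canonical PD order.
    """
    order = pd_order or {}
    best: dict[str, MatchPair] = {}
    for p in sorted(
        matches.pairs,
        key=lambda m: (
            abs(pd_values[m.pd_id] - gt_values[m.gt_id]),
            m.distance,
            order.get(m.pd_id, 0),
            m.pd_id,
        ),
    ):
        best.setdefault(p.gt_id, p)
    return MatchTable(matches.window_n, list(best.values()))
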