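"""Identification-event metrics.

True positives are predicted sites falling inside a window around any GT
site; false positives are predictions with no GT match; false negatives are
GT sites with no matching prediction.  Because TP is counted on the
prediction side while FN is counted on the GT side, sensitivity can exceed
1 when several predictions match one GT site; a GT-side TP count is
reported alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from intervaltree import IntervalTree

from pasbench.types import MatchTable, PasSet, TerminalExon


@dataclass
class IdentificationResult:
    window_n: int
    tp: int
    fp: int
    fn: int
    precision: float | None
    sensitivity: float | None
    jaccard: float | None
    tp_gt: int  # GT-side TP (matched GT sites), diagnostic alternate mode
    sensitivity_gt: float | None
    pct_genes_correct: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def identification_metrics(
    gt: PasSet, pd: PasSet, matches: MatchTable
) -> IdentificationResult:
    """Compute precision, sensitivity and Jaccard index from a match table.

    Empty inputs yield undefined (None) metrics rather than errors.
    """
    matched_pd = matches.matched_pd_ids()
    matched_gt = matches.matched_gt_ids()
    tp = len(matched_pd)
    fp = len(pd) - tp
    fn = len(gt) - len(matched_gt)
    tp_gt = len(matched_gt)
    return IdentificationResult(
        window_n=matches.window_n,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        jaccard=_ratio(tp, tp + fp + fn),
        tp_gt=tp_gt,
        sensitivity_gt=_ratio(tp_gt, tp_gt + fn),
    )


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def gene_extents(terminal_exons: list[TerminalExon]) -> list[GeneInterval]:
    """Union extent of each gene's terminal exons (one interval per
    gene/chrom/strand), a usable gene proxy when only TEs are at hand."""
    agg: dict[tuple[str, str, str], list[int]] = {}
    for te in terminal_exons:
        key = (te.gene_id, te.chrom, te.strand)
        if key in agg:
            agg[key][0] = min(agg[key][0], te.start)
            agg[key][1] = max(agg[key][1], te.end)
        else:
            agg[key] = [te.start, te.end]
    return [
        GeneInterval(g, c, se[0], se[1], s)
        for (g, c, s), se in sorted(agg.items())
    ]


def pct_genes_correct_pas(
    gt: PasSet, pd: PasSet, genes: list[GeneInterval]
) -> float | None:
    """Percentage of genes whose unique predicted PAS count equals the GT
    PAS count, over genes with at least one GT PAS.

    Sites are assigned to genes by strand-aware positional overlap with the
    gene extent; a site overlapping several genes counts for each.  Returns
    None when no gene has GT PAS.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g.gene_id)

    def counts(positions: set[tuple[str, int, str]]) -> dict[str, int]:
        out: dict[str, int] = {}
        for chrom, pos, strand in positions:
            tree = trees.get((chrom, strand))
            if tree is None:
                continue
            for iv in tree.at(pos):
                out[iv.data] = out.get(iv.data, 0) + 1
        return out

    gt_counts = counts({s.key for s in gt})
    pd_counts = counts({s.key for s in pd})  # unique PD sites
    considered = [g for g in gt_counts if gt_counts[g] >= 1]
    if not considered:
        return None
    correct = sum(1 for g in considered if pd_counts.get(g, 0) == gt_counts[g])
    return 100.0 * correct / len(considered)
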