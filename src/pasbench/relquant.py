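"""Relative-quantification metrics: poly(A) usage within composite terminal
exons.

Pipeline: (1) collapse the terminal exons (TEs) of each gene's transcripts
into composite TEs wherever they overlap; (2) attach ground-truth PAS to
composite TEs and compute each site's poly(A) usage (PAU) as its TPM over
the TE's total; (3) apply the high-confidence APA filter cascade (total
expression, minimum usage, top-2 dominance, minimum spacing) and label the
5'-most retained PAS proximal, the rest distal; (4) match predictions
(fractional-usage scores) to the retained GT-PAS and compare usage values
per match mode (all-PD / best-PD) and GT subset (all / proximal / distal).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from pasbench.io import validate_pau_set
from pasbench.matching import match_sites, select_best_pd
from pasbench.types import MatchTable, PasSet, PasSite, TerminalExon, ValidationError

MIN_PAIRS_FOR_CORRELATION = 20

SpacingRule = Literal["all_retained_pairs", "top2_only"]
Mode = Literal["all_pd", "best_pd"]
Subset = Literal["allPAS", "pPAS", "dPAS"]


@dataclass(frozen=True)
class RelFilterParams:
    """Thresholds of the high-confidence APA filter cascade.

    Defaults follow the benchmarking definition: a composite TE qualifies
    when its GT-PAS TPMs sum to >= 1, it keeps >= 2 PAS with usage >= 5%,
    the top two retained PAS carry >= 80% of usage, and retained PAS are
    >= 50 nt apart.
    """

    min_total_tpm: float = 1.0
    min_pau: float = 0.05
    top2_frac: float = 0.8
    min_pas_dist: int = 50
    spacing_rule: SpacingRule = "all_retained_pairs"

    def __post_init__(self) -> None:
        if min(self.min_total_tpm, self.min_pau, self.top2_frac, self.min_pas_dist) < 0:
            raise ValidationError("filter thresholds must be >= 0")
        if not self.min_pau < 1:
            raise ValidationError("min_pau must be < 1")
        if self.top2_frac > 1:
            raise ValidationError("top2_frac must be <= 1")


@dataclass(frozen=True)
class CompositeTE:
    te_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    member_tx_ids: tuple[str, ...]


@dataclass
class RetainedPas:
    site_id: str
    pos: int
    tpm: float
    pau: float


@dataclass
class QuantifiedTE:
    """A composite TE that passed the APA filter, with PAU-annotated GT-PAS."""

    composite: CompositeTE
    pas: list[RetainedPas]
    proximal_id: str
    distal_ids: list[str]


def build_composite_tes(tes: Iterable[TerminalExon]) -> list[CompositeTE]:
    """Merge transitively overlapping terminal exons of the same gene and
    strand into maximal composite intervals; non-overlapping TEs of one gene
    stay separate composites."""
    by_gene: dict[tuple[str, str, str], list[TerminalExon]] = {}
    for te in tes:
        by_gene.setdefault((te.gene_id, te.chrom, te.strand), []).append(te)
    composites: list[CompositeTE] = []
    for (gene_id, chrom, strand), group in sorted(by_gene.items()):
        group = sorted(group, key=lambda t: (t.start, t.end))
        cur = [group[0]]
        cur_end = group[0].end
        blocks: list[list[TerminalExon]] = []
        for te in group[1:]:
            if te.start < cur_end:  # strict overlap; adjacent TEs don't merge
                cur.append(te)
                cur_end = max(cur_end, te.end)
            else:
                blocks.append(cur)
                cur, cur_end = [te], te.end
        blocks.append(cur)
        for i, block in enumerate(blocks):
            composites.append(
                CompositeTE(
                    te_id=f"{gene_id}:TE{i + 1}",
                    gene_id=gene_id,
                    chrom=chrom,
                    start=min(t.start for t in block),
                    end=max(t.end for t in block),
                    strand=strand,
                    member_tx_ids=tuple(sorted(t.tx_id for t in block)),
                )
            )
    return composites


def compute_pau(tpms: Sequence[float]) -> np.ndarray:
    """Usage fractions tpm_i / sum(tpm); errors on an all-zero vector."""
    arr = np.asarray(tpms, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValidationError("cannot compute PAU: total TPM is zero")
    return arr / total


def _five_prime_distance(pos: int, te: CompositeTE) -> int:
    # distance from the strand-aware 5' boundary of the TE
    return pos - te.start if te.strand == "+" else te.end - 1 - pos


def label_proximal(te: CompositeTE, retained: list[RetainedPas]) -> tuple[str, list[str]]:
    """Proximal = retained PAS nearest the strand-aware 5' end of the TE;
    all others are distal."""
    ordered = sorted(retained, key=lambda r: (_five_prime_distance(r.pos, te), r.site_id))
    return ordered[0].site_id, [r.site_id for r in ordered[1:]]


@dataclass
class FilterAudit:
    """Per-step counts of composite TEs surviving the cascade."""

    n_input: int = 0
    n_with_pas: int = 0
    n_total_tpm: int = 0
    n_min_two_retained: int = 0
    n_top2: int = 0
    n_spacing: int = 0
    n_multi_te_pas: int = 0  # GT-PAS assigned to more than one composite TE


def filter_high_confidence(
    gt: PasSet,
    composites: Sequence[CompositeTE],
    params: RelFilterParams = RelFilterParams(),
) -> tuple[list[QuantifiedTE], FilterAudit]:
    """Apply the APA filter cascade to ground-truth PAS per composite TE.

    Steps, in order: collect same-strand GT-PAS overlapping the TE; require
    total TPM >= ``min_total_tpm``; compute PAU over that full denominator
    (never renormalized afterward); drop PAS with PAU < ``min_pau``; require
    >= 2 survivors; require the two largest PAUs to sum to >= ``top2_frac``;
    drop the TE if retained PAS violate the spacing rule; label
    proximal/distal.  A GT-PAS overlapping several composite TEs is assigned
    to each (counted in the audit).
    """
    audit = FilterAudit(n_input=len(composites))
    assignments: dict[str, int] = {}
    qtes: list[QuantifiedTE] = []
    for te in composites:
        members = [
            s
            for s in gt
            if s.chrom == te.chrom and s.strand == te.strand and te.start <= s.pos < te.end
        ]
        if not members:
            continue
        audit.n_with_pas += 1
        for s in members:
            assignments[s.site_id] = assignments.get(s.site_id, 0) + 1
        total = sum(s.score for s in members)
        if total < params.min_total_tpm:
            continue
        audit.n_total_tpm += 1
        paus = compute_pau([s.score for s in members])
        retained = [
            RetainedPas(s.site_id, s.pos, s.score, float(pau))
            for s, pau in zip(members, paus)
            if pau >= params.min_pau
        ]
        if len(retained) < 2:
            continue
        audit.n_min_two_retained += 1
        top2 = sum(sorted((r.pau for r in retained), reverse=True)[:2])
        if top2 < params.top2_frac:
            continue
        audit.n_top2 += 1
        if params.spacing_rule == "top2_only":
            spaced = sorted(retained, key=lambda r: r.pau, reverse=True)[:2]
        else:
            spaced = retained
        positions = sorted(r.pos for r in spaced)
        if any(b - a < params.min_pas_dist for a, b in zip(positions, positions[1:])):
            continue
        audit.n_spacing += 1
        retained.sort(key=lambda r: r.pos)
        proximal_id, distal_ids = label_proximal(te, retained)
        qtes.append(QuantifiedTE(te, retained, proximal_id, distal_ids))
    audit.n_multi_te_pas = sum(1 for n in assignments.values() if n > 1)
    return qtes, audit


@dataclass
class RelQuantResult:
    mode: Mode
    subset: Subset
    window_n: int
    n_pairs: int
    pearson_r: float | None
    abs_diffs: list[float]
    frac_te_any: float | None
    frac_te_ppas: float | None
    frac_te_dpas: float | None
    frac_te_both: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _gt_set_from_qtes(qtes: Sequence[QuantifiedTE]) -> tuple[PasSet, dict[str, float]]:
    """Retained GT-PAS as a matchable PasSet plus their PAU values.

    A PAS assigned to two composite TEs enters once (first assignment wins).
    """
    sites: list[PasSite] = []
    pau: dict[str, float] = {}
    for q in qtes:
        for r in q.pas:
            if r.site_id in pau:
                continue
            sites.append(
                PasSite(q.composite.chrom, r.pos, q.composite.strand, r.tpm, r.site_id)
            )
            pau[r.site_id] = r.pau
    return PasSet("qte_gt", "ground_truth", sites), pau


def rel_quant_metrics(
    qtes: Sequence[QuantifiedTE],
    pd: PasSet,
    window_n: int,
    mode: Mode = "all_pd",
    subset: Subset = "allPAS",
    ignore_strand: bool = False,
) -> RelQuantResult:
    """Compare predicted fractional usage against GT PAU over matched sites.

    No merging or splitting of predictions: in ``all_pd`` mode every matched
    (GT, PD) pair contributes a value (including duplicate PD coordinates);
    in ``best_pd`` mode only the PD whose usage is closest to the GT usage
    is kept per GT site.  Pearson correlation is reported only with at least
    20 pairs.  TE coverage fractions are computed over the full QuantifiedTE
    universe regardless of subset.
    """
    validate_pau_set(pd)
    gt_set, gt_pau = _gt_set_from_qtes(qtes)
    matches = match_sites(gt_set, pd, window_n, ignore_strand=ignore_strand)

    if mode == "best_pd":
        pd_values = {s.site_id: s.score for s in pd}
        pd_order = {s.site_id: i for i, s in enumerate(pd)}
        matches = select_best_pd(matches, gt_pau, pd_values, pd_order)

    subset_ids = _subset_ids(qtes, subset)
    pd_score = {s.site_id: s.score for s in pd}
    pairs = [
        (gt_pau[m.gt_id], pd_score[m.pd_id])
        for m in matches.pairs
        if m.gt_id in subset_ids
    ]
    abs_diffs = [abs(p - g) for g, p in pairs]
    pearson = None
    if len(pairs) >= MIN_PAIRS_FOR_CORRELATION:
        x = np.array([g for g, _ in pairs])
        y = np.array([p for _, p in pairs])
        if np.std(x) > 0 and np.std(y) > 0:
            pearson = float(stats.pearsonr(x, y).statistic)

    fr = _te_coverage(qtes, matches)
    return RelQuantResult(
        mode=mode,
        subset=subset,
        window_n=window_n,
        n_pairs=len(pairs),
        pearson_r=pearson,
        abs_diffs=abs_diffs,
        **fr,
    )


def _subset_ids(qtes: Sequence[QuantifiedTE], subset: Subset) -> set[str]:
    if subset == "allPAS":
        return {r.site_id for q in qtes for r in q.pas}
    if subset == "pPAS":
        return {q.proximal_id for q in qtes}
    if subset == "dPAS":
        return {d for q in qtes for d in q.distal_ids}
    raise ValidationError(f"unknown subset {subset!r}")


def _te_coverage(qtes: Sequence[QuantifiedTE], matches: MatchTable) -> dict:
    """Fractions of APA TEs with any / proximal / distal / both matches."""
    if not qtes:
        return dict(frac_te_any=None, frac_te_ppas=None, frac_te_dpas=None, frac_te_both=None)
    matched_gt = matches.matched_gt_ids()
    n = len(qtes)
    any_n = ppas_n = dpas_n = both_n = 0
    for q in qtes:
        p = q.proximal_id in matched_gt
        d = any(x in matched_gt for x in q.distal_ids)
        any_n += p or d
        ppas_n += p
        dpas_n += d
        both_n += p and d
    return dict(
        frac_te_any=any_n / n,
        frac_te_ppas=ppas_n / n,
        frac_te_dpas=dpas_n / n,
        frac_te_both=both_n / n,
    )


def ecdf(abs_diffs: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical CDF of absolute usage differences as sorted (x, F(x))
    steps; right-continuous and non-decreasing with F(max) = 1."""
    if len(abs_diffs) == 0:
        return []
    xs, counts = np.unique(np.asarray(abs_diffs, dtype=float), return_counts=True)
    cum = np.cumsum(counts) / len(abs_diffs)
    return [(float(x), float(f)) for x, f in zip(xs, cum)]
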