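"""Absolute-quantification metrics.

Predicted and ground-truth PAS carry TPM scores.  After optional expression
filtering (strictly greater than ``min_tpm`` on both sides) and
re-normalization of the predictions to a library of 1e6, sites are matched
within the window and predicted expression is split/merged onto the GT
sites.  Metrics: Pearson and Spearman correlation over matched (GT TPM,
aggregated PD TPM) pairs, pct-FP (percent of predicted TPM on sites with no
GT match), and precision / sensitivity / F1 from the match counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from pasbench.matching import match_sites, split_merge_expression
from pasbench.types import PasSet, PasSite


@dataclass
class AbsQuantResult:
    window_n: int
    min_tpm_filter: float
    n_matched: int
    pearson_r: float | None
    spearman_rho: float | None
    pct_fp: float | None
    tp: int
    fp: int
    fn: int
    precision: float | None
    sensitivity: float | None
    f1: float | None
    paired: list[tuple[str, float, float]] | None = None  # (gt_id, gt_tpm, pd_tpm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("paired")
        return d


def _filter_min_tpm(pas: PasSet, min_tpm: float) -> PasSet:
    return pas.replace_sites(s for s in pas if s.score > min_tpm)


def _renormalize(pas: PasSet, target: float = 1e6) -> PasSet:
    total = pas.total_score
    if total <= 0:
        return pas
    scale = target / total
    return pas.replace_sites(
        PasSite(s.chrom, s.pos, s.strand, s.score * scale, s.site_id) for s in pas
    )


def abs_quant_metrics(
    gt: PasSet,
    pd: PasSet,
    window_n: int,
    min_tpm: float = 0.0,
    renormalize: bool = True,
    log_scale: bool = False,
    ignore_strand: bool = False,
    keep_paired: bool = False,
) -> AbsQuantResult:
    """Compute the absolute-quantification metric suite.

    ``log_scale`` computes the correlations on log1p-transformed TPMs
    (correlation of ranks is unaffected).  Fewer than two matched GT sites
    leave the correlations undefined (None); the count-based metrics are
    reported regardless.
    """
    if min_tpm > 0:
        gt = _filter_min_tpm(gt, min_tpm)
        pd = _filter_min_tpm(pd, min_tpm)
    if renormalize:
        pd = _renormalize(pd)
    matches = match_sites(gt, pd, window_n, ignore_strand=ignore_strand)
    expr = split_merge_expression(matches, gt, pd)

    total_pd = pd.total_score
    pct_fp = 100.0 * expr.unmatched_pd_score / total_pd if total_pd > 0 else None

    gt_tpm = gt.by_id()
    pairs = sorted(expr.assigned.items())
    x = np.array([gt_tpm[g].score for g, _ in pairs], dtype=float)
    y = np.array([v for _, v in pairs], dtype=float)
    if log_scale:
        x, y = np.log1p(x), np.log1p(y)
    pearson = spearman = None
    if len(x) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)

    tp = len(matches.matched_pd_ids())
    fp = len(pd) - tp
    fn = len(gt) - len(matches.matched_gt_ids())
    precision = tp / (tp + fp) if tp + fp > 0 else None
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    f1_den = tp + 0.5 * (fp + fn)
    f1 = tp / f1_den if f1_den > 0 else None

    return AbsQuantResult(
        window_n=window_n,
        min_tpm_filter=min_tpm,
        n_matched=len(pairs),
        pearson_r=pearson,
        spearman_rho=spearman,
        pct_fp=pct_fp,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        paired=[(g, gt_tpm[g].score, v) for g, v in pairs] if keep_paired else None,
    )
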