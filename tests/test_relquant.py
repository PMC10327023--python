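"""Composite terminal exons, the APA filter cascade, and PAU metrics."""

import numpy as np
import pytest

from pasbench.relquant import (
    CompositeTE,
    RelFilterParams,
    build_composite_tes,
    compute_pau,
    ecdf,
    filter_high_confidence,
    label_proximal,
    rel_quant_metrics,
    RetainedPas,
)
from pasbench.types import PasSet, PasSite, TerminalExon, ValidationError
from tests.conftest import make_set


def te(start, end, tx="t1", gene="g1", strand="+"):
    return TerminalExon(tx, gene, "chr1", start, end, strand)


class TestCompositeTes:
    def test_overlapping_tes_merge(self):
        out = build_composite_tes([te(100, 400), te(300, 600, tx="t2")])
        assert [(c.start, c.end) for c in out] == [(100, 600)]
        assert out[0].member_tx_ids == ("t1", "t2")

    def test_disjoint_tes_stay_separate(self):
        out = build_composite_tes([te(100, 400), te(800, 900, tx="t2")])
        assert [(c.start, c.end) for c in out] == [(100, 400), (800, 900)]

    def test_chained_overlap_merges_transitively(self):
        out = build_composite_tes([te(100, 300), te(250, 500, tx="t2"), te(450, 700, tx="t3")])
        assert [(c.start, c.end) for c in out] == [(100, 700)]

    def test_adjacent_tes_do_not_merge(self):
        out = build_composite_tes([te(100, 400), te(400, 600, tx="t2")])
        assert len(out) == 2

    def test_same_gene_different_strand_kept_apart(self):
        out = build_composite_tes([te(100, 400), te(300, 600, tx="t2", strand="-")])
        assert len(out) == 2

    def test_composites_of_one_gene_never_overlap(self):
        rng = np.random.default_rng(5)
        tes = [
            te(int(s), int(s) + int(l), tx=f"t{i}")
            for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 40), rng.integers(50, 800, 40)))
        ]
        out = sorted(build_composite_tes(tes), key=lambda c: c.start)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start


class TestComputePau:
    @pytest.mark.parametrize(
        "tpms,expected",
        [([6, 3, 1], [0.6, 0.3, 0.1]), ([5], [1.0]), ([2, 2], [0.5, 0.5])],
    )
    def test_fractions(self, tpms, expected):
        out = compute_pau(tpms)
        assert out.tolist() == pytest.approx(expected)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            compute_pau([0, 0])


CTE = CompositeTE("g1:TE1", "g1", "chr1", 0, 1000, "+", ("t1",))


def gt_in_te(positions, tpms, strand="+"):
    return make_set(positions, scores=tpms, strand=strand)


class TestFilterCascade:
    def test_low_total_tpm_dropped(self):
        qtes, audit = filter_high_confidence(gt_in_te([100, 300], [0.4, 0.3]), [CTE])
        assert qtes == [] and audit.n_with_pas == 1 and audit.n_total_tpm == 0

    def test_worked_example_pau_cascade(self):
        # TPMs {10, 2, 0.4}: PAUs over denominator 12.4; the 0.4 site is <5%
        # and removed, top two sum to 0.96774 >= 0.8, two PAS retained
        qtes, _ = filter_high_confidence(gt_in_te([100, 300, 500], [10, 2, 0.4]), [CTE])
        (q,) = qtes
        assert [r.pau for r in q.pas] == pytest.approx([0.80645, 0.16129], abs=5e-6)
        assert sum(sorted((r.pau for r in q.pas), reverse=True)[:2]) == pytest.approx(0.96774, abs=5e-6)
        assert len(q.pas) == 2
        # PAU not renormalized after removal: retained usages sum below 1
        assert sum(r.pau for r in q.pas) < 1

    def test_close_spacing_drops_te(self):
        qtes, audit = filter_high_confidence(gt_in_te([100, 130], [5, 5]), [CTE])
        assert qtes == [] and audit.n_top2 == 1 and audit.n_spacing == 0

    def test_top2_dominance_required(self):
        # four equal sites: top2 = 0.5 < 0.8
        qtes, _ = filter_high_confidence(gt_in_te([100, 300, 500, 700], [5, 5, 5, 5]), [CTE])
        assert qtes == []

    def test_single_surviving_pas_dropped(self):
        qtes, _ = filter_high_confidence(gt_in_te([100, 300], [100, 1]), [CTE])
        assert qtes == []  # second site is <5% PAU, fewer than 2 remain

    def test_spacing_rule_top2_only(self):
        # three retained PAS: top-two (by PAU) are far apart, the third is close
        gt = gt_in_te([100, 130, 600], [5, 0.7, 5])
        params = RelFilterParams(top2_frac=0.8, spacing_rule="top2_only")
        qtes, _ = filter_high_confidence(gt, [CTE], params)
        assert len(qtes) == 1
        all_pairs, _ = filter_high_confidence(gt, [CTE])
        assert all_pairs == []

    def test_strand_mismatch_sites_ignored(self):
        qtes, audit = filter_high_confidence(gt_in_te([100, 300], [5, 5], strand="-"), [CTE])
        assert qtes == [] and audit.n_with_pas == 0

    @pytest.mark.parametrize(
        "param,values",
        [
            ("min_total_tpm", [0.5, 1, 5, 20, 100]),
            ("min_pau", [0.01, 0.05, 0.2, 0.4]),
            ("top2_frac", [0.5, 0.8, 0.9, 1.0]),
            ("min_pas_dist", [10, 50, 100, 121, 500]),
        ],
    )
    def test_cascade_monotone_in_thresholds(self, param, values):
        # GT sites spaced >= 120 nt apart, as produced by the ground-truth
        # preparation contract; without that spacing the PAU filter can
        # rescue a TE from the spacing filter and break monotonicity
        rng = np.random.default_rng(7)
        composites = [
            CompositeTE(f"g{i}:TE1", f"g{i}", "chr1", i * 5000, i * 5000 + 2000, "+", ())
            for i in range(40)
        ]
        sites = []
        for i in range(40):
            for k in range(int(rng.integers(1, 5))):
                pos = i * 5000 + k * 120 + int(rng.integers(0, 20))
                sites.append(PasSite("chr1", pos, "+", float(rng.lognormal(1, 1)), f"s{i}_{k}"))
        gt = PasSet("g", "ground_truth", sites)
        counts = [
            len(filter_high_confidence(gt, composites, RelFilterParams(**{param: v}))[0])
            for v in values
        ]
        assert counts == sorted(counts, reverse=True)


class TestLabelProximal:
    def test_plus_strand_five_prime_is_left(self):
        te_ = CompositeTE("x", "g", "chr1", 100, 600, "+", ())
        prox, distal = label_proximal(te_, [RetainedPas("a", 200, 1, 0.5), RetainedPas("b", 550, 1, 0.5)])
        assert prox == "a" and distal == ["b"]

    def test_minus_strand_five_prime_is_right(self):
        te_ = CompositeTE("x", "g", "chr1", 100, 600, "-", ())
        prox, distal = label_proximal(te_, [RetainedPas("a", 200, 1, 0.5), RetainedPas("b", 550, 1, 0.5)])
        assert prox == "b" and distal == ["a"]

    def test_three_pas_one_proximal(self):
        te_ = CompositeTE("x", "g", "chr1", 0, 1000, "+", ())
        prox, distal = label_proximal(
            te_,
            [RetainedPas("a", 150, 1, 0.4), RetainedPas("b", 300, 1, 0.3), RetainedPas("c", 580, 1, 0.3)],
        )
        assert prox == "a" and sorted(distal) == ["b", "c"]


def quantified_tes(n_te=30, pau=(0.6, 0.4), spacing=300):
    """Simple universe of + strand APA TEs with two retained PAS each."""
    composites, gt_sites = [], []
    for i in range(n_te):
        start = i * 5000
        composites.append(CompositeTE(f"g{i}:TE1", f"g{i}", "chr1", start, start + 2000, "+", ()))
        gt_sites.append(PasSite("chr1", start + 100, "+", 10 * pau[0], f"g{i}_p"))
        gt_sites.append(PasSite("chr1", start + 100 + spacing, "+", 10 * pau[1], f"g{i}_d"))
    gt = PasSet("g", "ground_truth", gt_sites)
    qtes, _ = filter_high_confidence(gt, composites)
    assert len(qtes) == n_te
    return qtes, gt


class TestRelQuantMetrics:
    def test_perfect_prediction(self):
        qtes, gt = quantified_tes(n_te=15)  # 30 pairs >= 20
        pd = PasSet(
            "p", "prediction",
            [PasSite(s.chrom, s.pos, s.strand, 0.6 if s.site_id.endswith("_p") else 0.4, "pd_" + s.site_id) for s in gt],
        )
        res = rel_quant_metrics(qtes, pd, 50)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.abs_diffs == pytest.approx([0.0] * res.n_pairs)
        assert res.frac_te_any == res.frac_te_ppas == res.frac_te_dpas == res.frac_te_both == 1.0

    @pytest.mark.parametrize("n_pairs,defined", [(19, False), (20, True)])
    def test_correlation_reporting_threshold(self, n_pairs, defined):
        # 10 TEs give 20 retained GT-PAS; predicting 19 of them stays below
        # the 20-matched-values reporting threshold
        qtes, gt = quantified_tes(n_te=10)
        rng = np.random.default_rng(3)
        sites = [
            PasSite(
                s.chrom, s.pos, s.strand,
                float(np.clip((0.6 if s.site_id.endswith("_p") else 0.4) + rng.normal(0, 0.05), 0, 1)),
                "pd_" + s.site_id,
            )
            for s in gt
        ][:n_pairs]
        res = rel_quant_metrics(qtes, PasSet("p", "prediction", sites), 50)
        assert res.n_pairs == n_pairs
        assert (res.pearson_r is not None) is defined
        assert len(res.abs_diffs) == res.n_pairs

    def test_all_pd_vs_best_pd_mode_semantics(self):
        qtes, gt = quantified_tes(n_te=1)
        # duplicate PD records at the proximal GT position with usages 0.4, 0.6; GT PAU 0.6
        prox = gt.sites[0] if gt.sites[0].site_id.endswith("_p") else gt.sites[1]
        pd = PasSet(
            "p", "prediction",
            [
                PasSite(prox.chrom, prox.pos, prox.strand, 0.4, "dup1"),
                PasSite(prox.chrom, prox.pos, prox.strand, 0.6, "dup2"),
            ],
        )
        all_pd = rel_quant_metrics(qtes, pd, 50, mode="all_pd", subset="pPAS")
        best_pd = rel_quant_metrics(qtes, pd, 50, mode="best_pd", subset="pPAS")
        assert sorted(all_pd.abs_diffs) == pytest.approx([0.0, 0.2])
        assert best_pd.abs_diffs == pytest.approx([0.0])

    def test_subset_restriction(self):
        qtes, gt = quantified_tes(n_te=5)
        pd = PasSet(
            "p", "prediction",
            [PasSite(s.chrom, s.pos, s.strand, 0.5, "pd_" + s.site_id) for s in gt if s.site_id.endswith("_p")],
        )
        res_p = rel_quant_metrics(qtes, pd, 50, subset="pPAS")
        res_d = rel_quant_metrics(qtes, pd, 50, subset="dPAS")
        assert res_p.n_pairs == 5 and res_d.n_pairs == 0
        assert res_p.frac_te_ppas == 1.0 and res_p.frac_te_dpas == 0.0 and res_p.frac_te_both == 0.0

    def test_coverage_fraction_ordering(self):
        qtes, gt = quantified_tes(n_te=10)
        rng = np.random.default_rng(4)
        keep = [s for s in gt if rng.uniform() < 0.6]
        pd = PasSet("p", "prediction", [PasSite(s.chrom, s.pos, s.strand, 0.5, "pd_" + s.site_id) for s in keep])
        res = rel_quant_metrics(qtes, pd, 50)
        assert res.frac_te_both <= min(res.frac_te_ppas, res.frac_te_dpas)
        assert max(res.frac_te_ppas, res.frac_te_dpas) <= res.frac_te_any

    def test_best_pd_never_more_pairs_or_larger_error(self):
        qtes, gt = quantified_tes(n_te=12)
        rng = np.random.default_rng(9)
        sites = []
        for s in gt:
            for k in range(int(rng.integers(1, 4))):
                sites.append(PasSite(s.chrom, s.pos, s.strand, float(rng.uniform(0, 1)), f"pd_{s.site_id}_{k}"))
        pd = PasSet("p", "prediction", sites)
        all_pd = rel_quant_metrics(qtes, pd, 50, mode="all_pd")
        best_pd = rel_quant_metrics(qtes, pd, 50, mode="best_pd")
        assert best_pd.n_pairs <= all_pd.n_pairs
        assert np.mean(best_pd.abs_diffs) <= np.mean(all_pd.abs_diffs) + 1e-12

    def test_pd_score_out_of_range_rejected(self):
        qtes, gt = quantified_tes(n_te=2)
        pd = PasSet("p", "prediction", [PasSite("chr1", 100, "+", 1.3, "bad")])
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            rel_quant_metrics(qtes, pd, 50)


class TestEcdf:
    def test_counting(self):
        assert ecdf([0.1, 0.1, 0.3]) == pytest.approx([(0.1, 2 / 3), (0.3, 1.0)])

    def test_all_zeros(self):
        assert ecdf([0.0, 0.0]) == [(0.0, 1.0)]

    def test_empty(self):
        assert ecdf([]) == []

    def test_monotone_and_bounded(self, rng):
        vals = rng.uniform(0, 1, 200)
        pts = ecdf(vals)
        fs = [f for _, f in pts]
        assert fs == sorted(fs) and 0 < fs[0] <= 1 and fs[-1] == pytest.approx(1.0)
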