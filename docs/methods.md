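# Methods

## Site matching

Ground-truth (GT) and predicted (PD) poly(A) sites are single nucleotides
in 0-based half-open BED coordinates; the BED start of the 1-nt interval is
the site coordinate. A PD site matches a GT site when both lie on the same
chromosome and strand and `|pd_pos − gt_pos| ≤ n`, i.e. the GT coordinate is
extended by `n` nt in both directions and the window is closed at both ends.
The preset window sizes are 10, 25, 50 and 100 nt; any non-negative `n` is
accepted. All qualifying pairs are kept (many-to-many). Matching is
strand-aware by default because cleavage sites are strand-specific;
`ignore_strand=True` restores plain positional intersection for
compatibility with strand-agnostic interval tooling. The engine indexes the
extended GT windows in an interval tree; `brute_force_match` is a separate
all-pairs implementation of the same predicate kept as a permanent test
oracle, and the two are asserted equal on randomized instances.

Each benchmarking event post-processes the match table differently:

- **Identification** uses the raw table: TP = distinct matched PD sites,
  FP = unmatched PD sites, FN = unmatched GT sites. TP is counted on the
  prediction side, so when several predictions hit one GT site the TP count
  exceeds the matched-GT count; a GT-side TP count (`tp_gt`,
  `sensitivity_gt`) is reported alongside as a diagnostic. With TP in its
  own denominator sensitivity stays in [0, 1] either way.
- **Absolute quantification** splits each PD site's TPM across its matched
  GT sites with weights proportional to `1/(d+1)`, then sums shares per GT
  site. The `+1` pseudo-distance makes a zero-distance match well defined
  and dominant without taking all mass when co-matched; the weight function
  is a configurable detail, and total predicted TPM is conserved exactly
  between per-GT aggregates and the unmatched remainder regardless of the
  choice.
- **Relative quantification** performs no splitting or merging. In `all_pd`
  mode every matched pair contributes one (GT usage, PD usage) value,
  duplicates included — methods that report the same coordinate once per
  transcript-level terminal exon legitimately produce duplicate records, and
  a user cannot know in advance which duplicate is right. In `best_pd` mode
  only the prediction whose usage value is closest to the GT usage is kept
  per GT site (ties break on smaller distance, then canonical PD order).

## Identification metrics

precision = TP/(TP+FP), sensitivity = TP/(TP+FN), Jaccard = TP/(TP+FP+FN);
undefined denominators yield null, never exceptions. The per-gene metric
assigns GT sites and *unique* PD sites (deduplicated on chromosome,
position, strand) to genes by strand-aware overlap with gene extents —
here the union of a gene's terminal exons, since no richer gene model is
required; a site overlapping several genes counts for each. Genes with no
GT site are excluded, and the metric is the percentage of remaining genes
whose PD count equals their GT count.

## Absolute quantification

Optionally, GT and PD sites with TPM ≤ `min_tpm` are removed before
matching (the threshold is strict, so the conventional "TPM > 1" filter is
`min_tpm=1`). Remaining PD scores are rescaled to sum to 1e6 — a
library-size normalization that makes methods with different score
conventions comparable; it is linear, hence invisible to Pearson, Spearman
and pct-FP, and `renormalize=False` disables it. Correlations are computed
on linear TPM by default with a `log_scale` (log1p) option, over GT sites
with at least one match; fewer than two matched sites (or zero variance)
leave them null. pct-FP = 100 × (TPM of unmatched PD sites) / (total PD
TPM), computed after filtering and before splitting. F1 uses the same
match-table counts as identification.

## Relative quantification

Composite terminal exons (TEs): per gene and strand, the strand-aware last
exons of all transcripts are merged transitively wherever they overlap
(strictly — abutting exons stay separate); a gene with non-overlapping TEs
contributes several composites.

High-confidence APA filter, applied per composite TE in this order:

1. collect same-strand GT sites inside the TE interval;
2. require ΣTPM ≥ `min_total_tpm` (default 1);
3. compute PAU_i = TPM_i / ΣTPM with the denominator over *all* TE sites —
   PAU is never renormalized after later removals, so retained usages may
   sum below 1;
4. remove sites with PAU < `min_pau` (default 5%) and require ≥ 2 survivors;
5. require the two largest PAUs to sum to ≥ `top2_frac` (default 80%);
6. drop the TE if retained sites are closer than `min_pas_dist` (default
   50 nt). The default `all_retained_pairs` rule checks every retained
   pair; `top2_only` checks just the two highest-usage sites, a laxer
   reading that is also in circulation. Both are provided because the
   narrative definitions differ between common usages;
7. label the retained site nearest the strand-aware 5′ end of the TE
   proximal (pPAS; smallest coordinate on "+", largest on "−"), the rest
   distal (dPAS).

Each step logs survivor counts (`FilterAudit`) for auditability. A GT site
overlapping composite TEs of two different genes is assigned to each and
counted in the audit; for matching, its first PAU assignment is used.

One non-obvious interaction: the cascade is *not* monotone in `min_pau` on
arbitrary inputs, because removing a low-usage site can rescue a TE from
the spacing filter. Monotonicity holds when sites within a TE respect the
2×`min_pas_dist` spacing that the ground-truth preparation and the
synthetic generator guarantee, which is the regime the monotonicity tests
run in.

Metrics per (window, mode, subset): matched usage pairs, |ΔPAU| values and
their eCDF, and Pearson r — reported only with ≥ 20 pairs, below which a
correlation is too unstable to compare methods on. TE coverage fractions
(any / pPAS / dPAS / both matched) are computed over the full filtered-TE
universe and satisfy both ≤ min(pPAS, dPAS) ≤ any.

## Ground-truth preparation

- **Internal-priming filter**: a site is discarded when the 10 nt
  immediately 3′ of it in transcript orientation (forward positions
  pos+1…pos+10 on "+", reverse-complemented pos−10…pos−1 on "−") contain
  ≥ 6 consecutive A or ≥ 7 A in total. The cleavage nucleotide itself is
  excluded from the window, since the artifact arises from templated
  A-stretches downstream of the reported site. Comparison is
  case-insensitive and 'N' never counts as 'A' (conservative on ambiguous
  sequence). Sites whose window would run off the chromosome are kept and
  flagged rather than judged on partial sequence.
- **Counts → TPM**: score × 1e6 / total; idempotent up to scale.
- **Cluster collapse**: multi-nucleotide PAS clusters become their summit
  when one is provided, otherwise the midpoint `floor((start+end−1)/2)`;
  cluster score is carried over unchanged. The representative rule is a
  policy argument because upstream clustering protocols differ.
- **Simulated GT from transcript quantifications**: the strand-aware last
  nucleotide of each quantified transcript (exon-union extent) becomes a
  GT site with the transcript's TPM; transcripts sharing that nucleotide
  merge with summed TPM; quantified transcripts missing from the GTF are
  reported, not fatal.

## Synthetic data

The generator emulates the *output* side of a benchmarking run — an
annotation, a genome, GT sites with expression, and predictions with
controlled errors — not read-level RNA-seq signal, coverage biases, or
annotation incompleteness. Passing tests therefore demonstrate that the
metrics measure what they claim on known error structure, not that any
real method achieves those values.

Geometry: genes alternate strands along one chromosome, each with
`tes_per_gene` single-exon transcripts of `te_length` nt (default 2000)
whose exon is its own terminal exon; `pas_per_te` GT sites (default 2) are
planted per TE. Sites are spaced `max(2·min_pas_dist, jitter_max + 103)` nt
apart and genes separated by ≥ 500 nt, so a jittered prediction can only
ever match its own site of origin and the discrete-jitter expectations
below are exact. Expression is `tpm_floor + LogNormal(tpm_logmean,
tpm_logsd)` (defaults 1 + LN(2, 1), a right-skewed site-level TPM
distribution with every TE passing the ΣTPM ≥ 1 filter by construction);
`equal_usage` gives all sites of a TE one draw, guaranteeing the usage
filter passes too.

Planted errors (deterministic counts, `round(rate·n)`, so noiseless
expectations are exact): `fn_rate` of GT sites get no prediction;
surviving predictions are jittered uniformly on [−jitter_max, +jitter_max];
`round(fp_rate · n_predictions)` false positives are planted ≥ jitter_max
+ 101 nt from every GT site (beyond the widest window preset, so they can
never match); predicted TPM gets multiplicative log-normal noise
(`tpm_noise_sd`) and predicted usage logit-normal noise (`usage_noise_sd` —
the logit scale keeps perturbed usages inside (0, 1) without clamping).
A `a_tract_fraction` of GT sites get a 10-nt A-tract written downstream in
the genome while all others get a fixed A-poor window, giving the priming
filter exact positive and negative cases.

Truth labels (per-prediction origin and jitter, per-GT coverage) make the
expected identification metrics analytic: a true prediction matches with
probability p = min(2n+1, 2j+1)/(2j+1) (e.g. 101/161 for window 50 against
jitter 80), so E[precision] = n_true·p/(n_true+n_fp) and E[sensitivity] =
n_true·p/n_gt, with 3·SE binomial tolerances that collapse to zero when
jitter is zero.

## Result records

Every computation serializes to a self-describing JSON record (event,
dataset, method, window, parameter echo, metrics, provenance with package
version and sha256 input digests). Records deliberately carry no wall-clock
timestamp so that identical inputs yield byte-identical records and
consolidation is idempotent. `consolidate` groups records by event and
dataset into per-method metric arrays, accepts its own output as input
unchanged, and rejects records that share a key but disagree in content.

## Problem sizes and numerical choices

Tests and the acceptance script use 100–500 genes (200–1000 GT sites),
400–1000 randomized matching instances and 10 generator seeds — sizes at
which binomial tolerances are tight (3·SE ≈ 0.05 at n = 1000) while the
whole suite runs in seconds. Mass conservation is asserted to 1e-9
relative; PAU sums to 1 within 1e-12 before filtering. Ties in best-PD
selection break on distance then canonical PD order; empty inputs
propagate as empty outputs or null metrics, never exceptions, except where
an operation is undefined (TPM conversion of an all-zero sample, PAU of an
all-zero TE).

## Limitations

Real annotations have multi-exon terminal exons, overlapping genes and
chromosome-edge sites in proportions the generator does not emulate; the
I/O layer handles them, but the analytic recovery results apply to the
planted error model only. The differential-usage event (comparing PAU
between conditions) is out of scope, as are read-level preprocessing and
method execution.
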