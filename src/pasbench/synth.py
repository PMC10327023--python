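"""Seeded synthetic fixtures: annotation, genome, ground truth and
predictions with planted error structure.

The generator lays out non-overlapping genes on one chromosome, each with
one or more single-exon transcripts whose exon doubles as the terminal
exon, and plants ground-truth PAS inside the terminal exons.  Predictions
are derived from the ground truth by dropping a controlled fraction of
sites (false negatives), jittering positions uniformly in
[-jitter_max, +jitter_max], planting false positives far from every GT
window, and perturbing expression (multiplicative log-normal) and usage
(logit-normal).  Truth labels record which prediction is a jittered true
site and which is planted, so expected precision and sensitivity are
analytic functions of the configuration.

Spacing guarantees make those expectations exact: consecutive GT sites are
separated by more than jitter_max + 100 nt (100 nt being the widest
matching window preset), so a jittered prediction can only ever match its
own site of origin, and planted false positives are at least
jitter_max + 101 nt away from every GT site, so they can never match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from pasbench.io import write_pas_bed
from pasbench.types import PasSet, PasSite, ValidationError

MAX_WINDOW_PRESET = 100
_SAFE_DOWNSTREAM = "CGTACGTACG"  # 2 A's: never triggers the priming rule


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic benchmarking scenario.

    Rates are fractions in [0, 1]; planted counts are deterministic
    (``round(rate * n)``) so noiseless scenarios have exact expectations.
    """

    seed: int = 0
    n_genes: int = 100
    tes_per_gene: int = 1
    pas_per_te: int = 2
    te_length: int = 2000
    jitter_max: int = 0
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    tpm_logmean: float = 2.0
    tpm_logsd: float = 1.0
    tpm_floor: float = 1.0
    tpm_noise_sd: float = 0.0
    usage_noise_sd: float = 0.0
    equal_usage: bool = False
    a_tract_fraction: float = 0.0
    chrom: str = "chr1"
    pas_margin: int = 20
    min_pas_dist: int = 50

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "a_tract_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.jitter_max < 0 or self.pas_per_te < 1 or self.n_genes < 1:
            raise ValidationError("invalid scenario geometry")

    @property
    def pas_spacing(self) -> int:
        """GT-PAS spacing inside a TE: at least twice the relative-quant
        minimum distance and wide enough that jitter cannot reach a
        neighbouring site's widest window."""
        return max(2 * self.min_pas_dist, self.jitter_max + MAX_WINDOW_PRESET + 2)

    @property
    def gene_gap(self) -> int:
        return max(500, 2 * (self.jitter_max + MAX_WINDOW_PRESET + 2))


@dataclass
class TruthLabels:
    """Per-site provenance emitted alongside the fixtures."""

    jitter_max: int
    # pd_id -> ("true_site", origin_gt_id, jitter) or ("planted_fp", "", 0)
    pd_labels: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    # gt_id -> "covered" | "dropped"
    gt_labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_true_pd(self) -> int:
        return sum(1 for l in self.pd_labels.values() if l[0] == "true_site")

    @property
    def n_planted_fp(self) -> int:
        return sum(1 for l in self.pd_labels.values() if l[0] == "planted_fp")

    @property
    def n_gt(self) -> int:
        return len(self.gt_labels)

    @property
    def n_dropped(self) -> int:
        return sum(1 for v in self.gt_labels.values() if v == "dropped")


@dataclass
class SyntheticDataset:
    scenario: SyntheticScenario
    gtf_text: str
    genome_seq: dict[str, str]
    gt: PasSet
    pd_identification: PasSet
    pd_tpm: PasSet
    pd_pau: PasSet
    truth: TruthLabels

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all fixtures; byte-identical across runs with one seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "genome": outdir / "genome.fa",
            "gt": outdir / "ground_truth.bed",
            "pd_identification": outdir / "pd_identification.bed",
            "pd_tpm": outdir / "pd_tpm.bed",
            "pd_pau": outdir / "pd_pau.bed",
        }
        paths["gtf"].write_text(self.gtf_text)
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome_seq.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_pas_bed(self.gt, paths["gt"])
        write_pas_bed(self.pd_identification, paths["pd_identification"])
        write_pas_bed(self.pd_tpm, paths["pd_tpm"])
        write_pas_bed(self.pd_pau, paths["pd_pau"])
        return paths


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate a full synthetic dataset from a scenario (deterministic
    under a fixed seed)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    span_needed = 2 * sc.pas_margin + (sc.pas_per_te - 1) * sc.pas_spacing
    if span_needed > sc.te_length:
        raise ValidationError(
            f"infeasible geometry: {sc.pas_per_te} PAS spaced {sc.pas_spacing} nt "
            f"need {span_needed} nt but te_length is {sc.te_length}"
        )

    gtf_lines: list[str] = []
    gt_sites: list[PasSite] = []
    te_of_gt: dict[str, int] = {}  # gt_id -> TE serial, for usage computation
    cursor = 1000
    te_serial = 0
    for gi in range(sc.n_genes):
        gene_id = f"g{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        for ti in range(sc.tes_per_gene):
            tx_id = f"{gene_id}.t{ti}"
            te_start, te_end = cursor, cursor + sc.te_length
            gtf_lines.append(
                f"{sc.chrom}\tpasbench\texon\t{te_start + 1}\t{te_end}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
            )
            # PAS ordered proximal -> distal along transcript orientation
            for k in range(sc.pas_per_te):
                if strand == "+":
                    pos = te_start + sc.pas_margin + k * sc.pas_spacing
                else:
                    pos = te_end - 1 - sc.pas_margin - k * sc.pas_spacing
                gt_id = f"gt_{gene_id}.t{ti}.p{k}"
                gt_sites.append(PasSite(sc.chrom, pos, strand, 0.0, gt_id))
                te_of_gt[gt_id] = te_serial
            te_serial += 1
            cursor = te_end + sc.gene_gap
        cursor += sc.gene_gap

    n_gt = len(gt_sites)

    # expression: floor + log-normal, optionally equal within a TE
    if sc.equal_usage:
        te_tpm = sc.tpm_floor + rng.lognormal(sc.tpm_logmean, sc.tpm_logsd, te_serial)
        tpms = np.array([te_tpm[te_of_gt[s.site_id]] for s in gt_sites])
    else:
        tpms = sc.tpm_floor + rng.lognormal(sc.tpm_logmean, sc.tpm_logsd, n_gt)
    gt_sites = [replace(s, score=float(t)) for s, t in zip(gt_sites, tpms)]
    gt = PasSet("synthetic_gt", "ground_truth", gt_sites)

    # ground-truth usage per TE (denominator over the TE's sites)
    te_totals: dict[int, float] = {}
    for s in gt_sites:
        te_totals[te_of_gt[s.site_id]] = te_totals.get(te_of_gt[s.site_id], 0.0) + s.score
    gt_pau = {s.site_id: s.score / te_totals[te_of_gt[s.site_id]] for s in gt_sites}

    truth = TruthLabels(jitter_max=sc.jitter_max)

    # false negatives: deterministic count, random subset
    n_drop = round(sc.fn_rate * n_gt)
    drop_idx = set(rng.choice(n_gt, size=n_drop, replace=False).tolist()) if n_drop else set()
    covered: list[tuple[PasSite, int]] = []  # (gt site, jitter)
    for i, s in enumerate(gt_sites):
        if i in drop_idx:
            truth.gt_labels[s.site_id] = "dropped"
            continue
        truth.gt_labels[s.site_id] = "covered"
        jit = int(rng.integers(-sc.jitter_max, sc.jitter_max + 1)) if sc.jitter_max else 0
        covered.append((s, jit))

    pd_ident: list[PasSite] = []
    pd_tpm: list[PasSite] = []
    pd_pau: list[PasSite] = []
    for s, jit in covered:
        pd_id = f"pd_{s.site_id[3:]}"
        pos = s.pos + jit
        truth.pd_labels[pd_id] = ("true_site", s.site_id, jit)
        pd_ident.append(PasSite(sc.chrom, pos, s.strand, 0.0, pd_id))
        noise = math.exp(rng.normal(0.0, sc.tpm_noise_sd)) if sc.tpm_noise_sd else 1.0
        pd_tpm.append(PasSite(sc.chrom, pos, s.strand, s.score * noise, pd_id))
        pau = gt_pau[s.site_id]
        if sc.usage_noise_sd:
            pau = float(_sigmoid(_logit(np.array(pau)) + rng.normal(0.0, sc.usage_noise_sd)))
        pd_pau.append(PasSite(sc.chrom, pos, s.strand, pau, pd_id))

    # planted false positives in a zone beyond the last gene
    n_fp = round(sc.fp_rate * len(covered))
    fp_zone = cursor + sc.jitter_max + MAX_WINDOW_PRESET + 500
    for i in range(n_fp):
        pd_id = f"fp_{i:05d}"
        pos = fp_zone + i * (2 * MAX_WINDOW_PRESET + 50)
        strand = "+" if i % 2 == 0 else "-"
        truth.pd_labels[pd_id] = ("planted_fp", "", 0)
        score = float(sc.tpm_floor + rng.lognormal(sc.tpm_logmean, sc.tpm_logsd))
        pd_ident.append(PasSite(sc.chrom, pos, strand, 0.0, pd_id))
        pd_tpm.append(PasSite(sc.chrom, pos, strand, score, pd_id))
        pd_pau.append(PasSite(sc.chrom, pos, strand, float(rng.uniform()), pd_id))

    chrom_len = fp_zone + max(n_fp, 1) * (2 * MAX_WINDOW_PRESET + 50) + 500
    seq = _build_genome(sc, rng, chrom_len, gt_sites)

    return SyntheticDataset(
        scenario=sc,
        gtf_text="\n".join(gtf_lines) + "\n",
        genome_seq={sc.chrom: seq},
        gt=gt,
        pd_identification=PasSet("synthetic_pd", "prediction", pd_ident),
        pd_tpm=PasSet("synthetic_pd_tpm", "prediction", pd_tpm),
        pd_pau=PasSet("synthetic_pd_pau", "prediction", pd_pau),
        truth=truth,
    )


def _build_genome(
    sc: SyntheticScenario, rng: np.random.Generator, chrom_len: int, gt_sites: Sequence[PasSite]
) -> str:
    """Random ACGT sequence with controlled downstream windows: a chosen
    fraction of GT sites get a planted 10-nt A-tract (internal-priming
    positives by construction); all others get a fixed A-poor window."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=chrom_len).tolist()
    n_tract = round(sc.a_tract_fraction * len(gt_sites))
    tract_idx = set(rng.choice(len(gt_sites), size=n_tract, replace=False).tolist()) if n_tract else set()
    for i, s in enumerate(gt_sites):
        window = "A" * 10 if i in tract_idx else _SAFE_DOWNSTREAM
        if s.strand == "+":
            start = s.pos + 1
            seq[start : start + 10] = list(window)
        else:
            # reverse-complement of the oriented window on the forward strand
            comp = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            seq[s.pos - 10 : s.pos] = list(comp)
    return "".join(seq)


@dataclass
class ExpectedMetrics:
    """Analytic expectations for identification metrics under the planted
    error structure, with 3-standard-error tolerances for the stochastic
    jitter component (zero tolerance in the noiseless limit)."""

    window_n: int
    match_probability: float
    expected_precision: float | None
    expected_sensitivity: float | None
    tol_match_fraction: float
    tol_precision: float
    tol_sensitivity: float


def expected_metrics(truth: TruthLabels, window_n: int) -> ExpectedMetrics:
    """Expected precision/sensitivity from truth labels.

    A true prediction matches only its site of origin (spacing guarantee),
    with probability p = min(2w+1, 2j+1) / (2j+1) under uniform jitter on
    [-j, j]; planted false positives never match.  Hence
    E[precision] ~ n_true p / (n_true p + n_fp + n_true (1-p)) and
    E[sensitivity] ~ n_true p / n_gt.
    """
    j, n_true, n_fp, n_gt = truth.jitter_max, truth.n_true_pd, truth.n_planted_fp, truth.n_gt
    p = 1.0 if j == 0 else min(2 * window_n + 1, 2 * j + 1) / (2 * j + 1)
    se = math.sqrt(p * (1 - p) / n_true) if n_true else 0.0
    exp_tp = n_true * p
    precision = exp_tp / (n_true + n_fp) if (n_true + n_fp) else None
    sensitivity = exp_tp / n_gt if n_gt else None
    return ExpectedMetrics(
        window_n=window_n,
        match_probability=p,
        expected_precision=precision,
        expected_sensitivity=sensitivity,
        tol_match_fraction=3 * se,
        tol_precision=3 * se * n_true / (n_true + n_fp) if (n_true + n_fp) else 0.0,
        tol_sensitivity=3 * se * n_true / n_gt if n_gt else 0.0,
    )


def exact_counts_from_truth(truth: TruthLabels, window_n: int) -> tuple[int, int, int]:
    """Exact (tp, fp, fn) implied by the realized jitters — a brute-force
    oracle independent of the matching engine."""
    tp = sum(
        1
        for kind, _, jit in truth.pd_labels.values()
        if kind == "true_site" and abs(jit) <= window_n
    )
    fp = len(truth.pd_labels) - tp
    matched_gt = {
        origin
        for kind, origin, jit in truth.pd_labels.values()
        if kind == "true_site" and abs(jit) <= window_n
    }
    fn = truth.n_gt - len(matched_gt)
    return tp, fp, fn


def save_scenario(sc: SyntheticScenario, path: str | Path) -> None:
    """Flat key = value config file."""
    with open(path, "w") as fh:
        for k, v in asdict(sc).items():
            fh.write(f"{k} = {v}\n")


def load_scenario(path: str | Path) -> SyntheticScenario:
    kwargs: dict = {}
    fields = {f: t for f, t in SyntheticScenario.__annotations__.items()}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        k, v = (x.strip() for x in line.split("=", 1))
        if k not in fields:
            raise ValidationError(f"{path}:{lineno}: unknown scenario key {k!r}")
        ann = fields[k]
        if ann == "bool":
            kwargs[k] = v.lower() in ("true", "1", "yes")
        elif ann == "int":
            kwargs[k] = int(v)
        elif ann == "float":
            kwargs[k] = float(v)
        else:
            kwargs[k] = v
    return SyntheticScenario(**kwargs)
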