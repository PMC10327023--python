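"""Ground-truth preparation: internal-priming filtering, count-to-TPM
conversion, and cluster collapse.

Internal priming is the classic oligo(dT) artifact: a putative cleavage site
followed by a genomically templated A-stretch is more likely a priming event
inside the transcript body than a true poly(A) site.  Sites are discarded if
the 10 nt immediately downstream (transcript orientation) contain six
consecutive adenosines or at least seven in total.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable, Literal

from pyfaidx import Fasta

from pasbench.types import PasCluster, PasSet, PasSite, ValidationError

IP_WINDOW = 10
IP_MAX_RUN = 6
IP_MAX_TOTAL = 7

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_internal_priming(downstream: str, max_run: int = IP_MAX_RUN, max_total: int = IP_MAX_TOTAL) -> bool:
    """Apply the A-content rule to an already-oriented downstream sequence.

    Case-insensitive; 'N' never counts as 'A'.
    """
    seq = downstream.upper()
    if seq.count("A") >= max_total:
        return True
    return "A" * max_run in seq


def downstream_window(site: PasSite, genome: Fasta, length: int = IP_WINDOW) -> str | None:
    """The ``length``-nt genomic window immediately 3' of the site in
    transcript orientation, excluding the cleavage nucleotide.  Returns None
    if the window would run off the chromosome."""
    if site.chrom not in genome:
        raise ValidationError(f"chromosome {site.chrom!r} absent from genome FASTA")
    chrom_len = len(genome[site.chrom])
    if site.strand == "+":
        start, end = site.pos + 1, site.pos + 1 + length
        if end > chrom_len:
            return None
        return str(genome[site.chrom][start:end])
    start, end = site.pos - length, site.pos
    if start < 0:
        return None
    return _revcomp(str(genome[site.chrom][start:end]))


def internal_priming_filter(
    sites: PasSet, genome: str | Path | Fasta
) -> tuple[PasSet, PasSet, list[str]]:
    """Partition a PasSet into (kept, discarded) by the internal-priming rule.

    Sites whose downstream window extends past the chromosome end are kept
    and flagged (their ids are returned as the third element).
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    kept: list[PasSite] = []
    discarded: list[PasSite] = []
    flagged: list[str] = []
    for site in sites:
        window = downstream_window(site, fa)
        if window is None:
            kept.append(site)
            flagged.append(site.site_id)
        elif is_internal_priming(window):
            discarded.append(site)
        else:
            kept.append(site)
    return (
        sites.replace_sites(kept),
        sites.replace_sites(discarded),
        flagged,
    )


def write_discarded_bed(discarded: PasSet, path: str | Path, reason: str = "internal_priming") -> None:
    """Side BED of discarded sites with the reason tagged onto the name."""
    with open(path, "w") as fh:
        for s in discarded:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.site_id}|{reason}\t{s.score}\t{s.strand}\n")


def counts_to_tpm(sites: PasSet) -> PasSet:
    """Convert raw per-site read counts to TPM: count * 1e6 / total."""
    total = sites.total_score
    if total <= 0:
        raise ValidationError(f"sample {sites.sample_id!r}: total count is zero")
    scale = 1e6 / total
    return sites.replace_sites(
        PasSite(s.chrom, s.pos, s.strand, s.score * scale, s.site_id) for s in sites
    )


RepresentativeRule = Literal["summit_else_midpoint", "midpoint"]


def _midpoint(c: PasCluster) -> int:
    return (c.start + c.end - 1) // 2


def representative_position(cluster: PasCluster, rule: RepresentativeRule = "summit_else_midpoint") -> int:
    if rule == "summit_else_midpoint" and cluster.summit is not None:
        return cluster.summit
    return _midpoint(cluster)


def collapse_clusters(
    clusters: Iterable[PasCluster],
    rule: RepresentativeRule = "summit_else_midpoint",
    sample_id: str = "collapsed",
    role: str = "ground_truth",
) -> PasSet:
    """Collapse PAS clusters to single-nucleotide representative sites.

    The representative is the cluster summit when provided, otherwise the
    midpoint ``floor((start + end - 1) / 2)``; the cluster's total score is
    carried over unchanged.
    """
    sites = []
    for i, c in enumerate(clusters):
        pos = representative_position(c, rule)
        site_id = c.cluster_id or f"{c.chrom}:{pos}:{c.strand}"
        sites.append(PasSite(c.chrom, pos, c.strand, c.total_score, site_id))
    return PasSet(sample_id, role, sites)
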