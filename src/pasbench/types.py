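"""Core domain types.

All genomic coordinates are 0-based half-open (BED convention).  A poly(A)
site (PAS) is a single nucleotide, so its BED interval is [pos, pos + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

VALID_STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An input record violates a format or domain invariant."""


@dataclass(frozen=True)
class PasSite:
    """A single-nucleotide poly(A) site.

    ``pos`` is the 0-based genomic coordinate of the cleavage nucleotide;
    ``score`` carries TPM for absolute quantification, fractional usage in
    [0, 1] for relative quantification, and is ignored for identification.
    """

    chrom: str
    pos: int
    strand: str
    score: float = 0.0
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"site {self.site_id!r}: negative position {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"site {self.site_id!r}: bad strand {self.strand!r}")
        if not (math.isfinite(self.score) and self.score >= 0):
            raise ValidationError(f"site {self.site_id!r}: bad score {self.score!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.strand, self.site_id)


@dataclass
class PasSet:
    """An ordered collection of PAS in a ground-truth or prediction role."""

    sample_id: str
    role: str  # "ground_truth" | "prediction"
    sites: list[PasSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("ground_truth", "prediction"):
            raise ValidationError(f"bad role {self.role!r}")
        self.sites = sorted(self.sites, key=PasSite.sort_key)
        seen: set[str] = set()
        for s in self.sites:
            if s.site_id in seen:
                raise ValidationError(f"duplicate site_id {s.site_id!r} in {self.sample_id!r}")
            seen.add(s.site_id)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[PasSite]:
        return iter(self.sites)

    @property
    def total_score(self) -> float:
        return float(sum(s.score for s in self.sites))

    def by_id(self) -> dict[str, PasSite]:
        return {s.site_id: s for s in self.sites}

    def replace_sites(self, sites: Iterable[PasSite]) -> "PasSet":
        return PasSet(self.sample_id, self.role, list(sites))


@dataclass(frozen=True)
class TerminalExon:
    """The strand-aware last exon of a transcript (0-based half-open)."""

    tx_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"terminal exon {self.tx_id}: start >= end")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"terminal exon {self.tx_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PasCluster:
    """A multi-nucleotide PAS cluster to be collapsed to one representative site."""

    chrom: str
    start: int
    end: int
    strand: str
    total_score: float = 0.0
    summit: int | None = None
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"cluster {self.cluster_id}: start >= end")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(f"cluster {self.cluster_id}: summit outside span")


@dataclass(frozen=True)
class MatchPair:
    pd_id: str
    gt_id: str
    distance: int


@dataclass
class MatchTable:
    """All (PD, GT) pairs with |pd_pos - gt_pos| <= window_n on the same
    chromosome and strand.  Many-to-many pairs are kept; every metric module
    consumes this table."""

    window_n: int
    pairs: list[MatchPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_n < 0:
            raise ValidationError("window_n must be >= 0")
        keys = [(p.pd_id, p.gt_id) for p in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (pd_id, gt_id) pair in match table")
        self.pairs = sorted(self.pairs, key=lambda p: (p.pd_id, p.gt_id))

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[str, str, int]]:
        return {(p.pd_id, p.gt_id, p.distance) for p in self.pairs}

    def matched_pd_ids(self) -> set[str]:
        return {p.pd_id for p in self.pairs}

    def matched_gt_ids(self) -> set[str]:
        return {p.gt_id for p in self.pairs}

    def by_pd(self) -> dict[str, list[MatchPair]]:
        out: dict[str, list[MatchPair]] = {}
        for p in self.pairs:
            out.setdefault(p.pd_id, []).append(p)
        return out

    def by_gt(self) -> dict[str, list[MatchPair]]:
        out: dict[str, list[MatchPair]] = {}
        for p in self.pairs:
            out.setdefault(p.gt_id, []).append(p)
        return out

    def to_tsv(self) -> str:
        lines = ["pd_id\tgt_id\tdistance"]
        lines += [f"{p.pd_id}\t{p.gt_id}\t{p.distance}" for p in self.pairs]
        return "\n".join(lines) + "\n"


@dataclass
class GtAssignedExpression:
    """Predicted expression aggregated onto GT sites after the
    split (one PD to many GT) / merge (many PD to one GT) step."""

    assigned: dict[str, float]
    unmatched_pd_score: float

    @property
    def total(self) -> float:
        return float(sum(self.assigned.values()) + self.unmatched_pd_score)
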