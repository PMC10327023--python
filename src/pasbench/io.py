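"""Reading, writing and validating the interchange formats.

BED6 carries PAS (single-nucleotide intervals; the score column holds TPM or
fractional usage depending on the benchmarking event), GTF carries gene
models, and transcript quantifications arrive as tab-separated tables with a
header naming ``transcript_id`` and ``tpm`` columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pyranges

from pasbench.types import PasSet, PasSite, TerminalExon, ValidationError


class BedParseError(ValueError):
    """A BED line could not be parsed; the message carries the line number."""


def _format_score(score: float) -> str:
    # full precision, but keep integers tidy
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_pas_bed(path: str | Path, role: str, sample_id: str | None = None) -> PasSet:
    """Read a BED6 file of single-nucleotide poly(A) sites.

    Every record must satisfy ``end == start + 1``; wider intervals indicate
    an uncollapsed cluster file and are rejected (run the ground-truth
    collapse first).  Missing names (``.``) are synthesized as
    ``chrom:pos:strand``.  Duplicate (chrom, pos, strand) records are
    rejected for ground truth (a GT must be a site *set*); for predictions
    they are kept as independent candidate records with disambiguated ids,
    because transcript-level methods legitimately report the same coordinate
    more than once.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    sites: list[PasSite] = []
    seen_ids: dict[str, int] = {}
    seen_keys: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            if end != start + 1:
                raise ValidationError(
                    f"{path}:{lineno}: record {name!r} spans {end - start} nt; "
                    "PAS must be single-nucleotide (collapse clusters first)"
                )
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: strand {strand!r} not in {{+,-}}")
            key = (chrom, start, strand)
            if key in seen_keys and role == "ground_truth":
                raise ValidationError(
                    f"{path}:{lineno}: duplicate ground-truth site at {chrom}:{start}:{strand}"
                )
            seen_keys.add(key)
            site_id = name if name != "." else f"{chrom}:{start}:{strand}"
            if site_id in seen_ids:
                seen_ids[site_id] += 1
                site_id = f"{site_id}#{seen_ids[site_id]}"
            else:
                seen_ids[site_id] = 0
            try:
                sites.append(PasSite(chrom, start, strand, score, site_id))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return PasSet(sample_id, role, sites)


def write_pas_bed(pas_set: PasSet, path: str | Path) -> None:
    """Write a PasSet as BED6 in canonical sort order; round-trips with
    :func:`read_pas_bed`."""
    with open(path, "w") as fh:
        for s in pas_set:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.site_id}\t{_format_score(s.score)}\t{s.strand}\n"
            )


def _read_gtf_exons(gtf_path: str | Path) -> pd.DataFrame:
    """Exon features of a GTF as a DataFrame with 0-based half-open Start/End."""
    gr = pyranges.read_gtf(str(gtf_path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    exons = df[df["Feature"] == "exon"].copy()
    if len(exons) == 0:
        return exons
    for col in ("transcript_id", "gene_id"):
        if col not in exons.columns or exons[col].isna().any() or (exons[col] == "").any():
            raise ValidationError(f"{gtf_path}: exon feature missing {col} attribute")
    exons["Chromosome"] = exons["Chromosome"].astype(str)
    return exons


def read_terminal_exons(gtf_path: str | Path) -> list[TerminalExon]:
    """Extract the strand-aware last exon of every transcript in a GTF.

    On "+" the terminal exon is the highest-coordinate exon, on "-" the
    lowest-coordinate one.  Transcripts without exon features are skipped
    with a warning.
    """
    exons = _read_gtf_exons(gtf_path)
    tes: list[TerminalExon] = []
    if len(exons) == 0:
        warnings.warn(f"{gtf_path}: no exon features found")
        return tes
    for (tx_id, gene_id, chrom, strand), grp in exons.groupby(
        ["transcript_id", "gene_id", "Chromosome", "Strand"], sort=True, observed=True
    ):
        if strand == "+":
            row = grp.loc[grp["End"].idxmax()]
        else:
            row = grp.loc[grp["Start"].idxmin()]
        tes.append(
            TerminalExon(
                tx_id=str(tx_id),
                gene_id=str(gene_id),
                chrom=str(chrom),
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=str(strand),
            )
        )
    tes.sort(key=lambda t: (t.chrom, t.start, t.end, t.tx_id))
    return tes


def read_transcript_quant(path: str | Path) -> dict[str, float]:
    """Read a transcript quantification table (TSV with a header; columns
    ``transcript_id`` and ``tpm``, case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "transcript_id" not in cols or "tpm" not in cols:
        raise ValidationError(f"{path}: need 'transcript_id' and 'tpm' columns, found {list(df.columns)}")
    return dict(
        zip(df[cols["transcript_id"]].astype(str), df[cols["tpm"]].astype(float))
    )


def gt_from_transcript_quant(
    quant: Mapping[str, float],
    gtf_path: str | Path,
    sample_id: str = "simulated_gt",
) -> tuple[PasSet, list[str]]:
    """Derive a ground-truth PasSet from transcript-level TPMs.

    The last nucleotide of each quantified transcript is taken as its
    poly(A) site: in 0-based coordinates the position ``end - 1`` on "+" and
    ``start`` on "-", where [start, end) is the transcript extent (union of
    its exons).  Transcripts sharing a (chrom, pos, strand) merge with
    summed TPM.  Returns the PasSet and the list of quantified transcript
    ids absent from the annotation (reported, not fatal).
    """
    exons = _read_gtf_exons(gtf_path)
    extents: dict[str, tuple[str, int, int, str]] = {}
    if len(exons) > 0:
        agg = exons.groupby("transcript_id").agg(
            Chromosome=("Chromosome", "first"),
            Start=("Start", "min"),
            End=("End", "max"),
            Strand=("Strand", "first"),
        )
        extents = {
            str(tx): (str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand))
            for tx, r in agg.iterrows()
        }
    merged: dict[tuple[str, int, str], float] = {}
    skipped: list[str] = []
    for tx_id in sorted(quant):
        tpm = float(quant[tx_id])
        if tx_id not in extents:
            skipped.append(tx_id)
            continue
        chrom, start, end, strand = extents[tx_id]
        pos = end - 1 if strand == "+" else start
        key = (chrom, pos, strand)
        merged[key] = merged.get(key, 0.0) + tpm
    sites = [
        PasSite(chrom, pos, strand, score, f"{chrom}:{pos}:{strand}")
        for (chrom, pos, strand), score in merged.items()
    ]
    return PasSet(sample_id, "ground_truth", sites), skipped


def validate_pau_set(pas_set: PasSet) -> None:
    """Relative-usage predictions must have scores in [0, 1]."""
    for s in pas_set:
        if not 0.0 <= s.score <= 1.0:
            raise ValidationError(
                f"site {s.site_id!r}: fractional usage {s.score} outside [0, 1]"
            )


def write_pas_sets_equal(a: PasSet, b: PasSet) -> bool:
    return [
        (s.chrom, s.pos, s.strand, s.score, s.site_id) for s in a
    ] == [(s.chrom, s.pos, s.strand, s.score, s.site_id) for s in b]
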