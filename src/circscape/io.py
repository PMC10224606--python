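"""Readers and writers for GTF, BED, FASTA and the pipeline's TSV tables.

GTF is 1-based fully-closed on disk and converted to the internal 0-based
half-open convention on read (and back on write). BED is already 0-based
half-open and passes through unchanged. All TSV tables are tab-separated
with a header row, UTF-8.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from circscape.intervals import (
    AluElement,
    CoordinateError,
    GenomicInterval,
    TranscriptModel,
)

PathLike = Union[str, Path]

__all__ = [
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "fetch_seq",
    "read_repeats",
    "write_repeats",
    "read_tsv",
    "write_tsv",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: PathLike) -> list[TranscriptModel]:
    """Read transcripts from an Ensembl-dialect GTF.

    Only ``exon`` features are used; each needs ``gene_id`` and
    ``transcript_id`` attributes (``gene_name`` falls back to ``gene_id``).
    Coordinates are converted 1-based inclusive -> 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, CoordinateError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attrs = _parse_gtf_attributes(attr)
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: missing attribute {exc.args[0]}"
                ) from exc
            gname = attrs.get("gene_name", gid)
            exons.setdefault(tid, []).append(iv)
            meta[tid] = (gid, gname, strand)
    out = []
    for tid, ivs in exons.items():
        gid, gname, strand = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname,
                strand=strand,
                exons=tuple(ivs),
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: PathLike) -> None:
    """Write transcripts as Ensembl-dialect GTF (exon features only)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tx in transcripts:
            for i, e in enumerate(tx.exons, 1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{tx.gene_name}"; exon_number "{i}";'
                )
                fh.write(
                    f"{e.chrom}\tcircscape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 as intervals (strand honoured when present)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except (ValueError, CoordinateError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    records: Iterable[GenomicInterval | tuple[GenomicInterval, str]],
    path: PathLike,
) -> None:
    """Write intervals (or ``(interval, name)`` pairs) as BED6."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            iv, name = rec if isinstance(rec, tuple) else (rec, ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def fetch_seq(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Slice ``chrom[start:end]`` from a genome mapping (0-based half-open)."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
    return str(seq[start:end]).upper()


def read_repeats(path: PathLike, family_prefix: str | None = None) -> list[AluElement]:
    """Read a RepeatMasker-derived BED6/TSV (name column = repeat family).

    ``family_prefix`` keeps only elements whose family starts with the prefix
    (e.g. ``"Alu"``), mirroring a grep on the repeat annotation.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6 with family name")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            except (ValueError, CoordinateError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            family = fields[3]
            if family_prefix is None or family.startswith(family_prefix):
                out.append(AluElement(interval=iv, family=family))
    return out


def write_repeats(repeats: Iterable[AluElement], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.family}\t0\t{iv.strand}\n")


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
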