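"""Unified circRNA catalog from multi-detector back-spliced junction calls.

Per-detector call tables are merged on BSJ coordinates, filtered on
expression and detector support, annotated against transcript models and a
known-circRNA lookup, and summarised per host gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from circscape.intervals import GenomicInterval, TranscriptModel, to_1based

logger = logging.getLogger(__name__)

__all__ = [
    "BsjCall",
    "CircRNA",
    "CatalogSummary",
    "merge_bsj_calls",
    "filter_expression",
    "filter_detector_support",
    "annotate_splice_status",
    "host_gene_summary",
    "read_detector_table",
    "catalog_to_frame",
]

DEFAULT_DETECTOR_PRIORITY = ("circexplorer2", "ciri2", "mapsplice")


@dataclass(frozen=True)
class BsjCall:
    """One detector's call of a back-spliced junction."""

    interval: GenomicInterval
    detector_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class CircRNA:
    """A merged back-spliced junction record.

    ``annotation`` is ``"annotated"`` when both BSJ ends coincide exactly with
    exon boundaries of one transcript, else ``"de_novo"``; ``bs_exon_indices``
    holds the 0-based indices of the back-spliced boundary exons in the
    assigned transcript's ascending-genomic exon list.
    """

    interval: GenomicInterval
    detectors: frozenset[str]
    counts: tuple[int, ...]
    host_gene: str = "intergenic"
    annotation: str = "de_novo"
    known_id: Optional[str] = None
    transcript_id: Optional[str] = None
    bs_exon_indices: Optional[tuple[int, int]] = None
    strand_conflict: bool = False

    @property
    def circ_id(self) -> str:
        chrom, s1, e1 = to_1based(self.interval)
        return f"{self.host_gene}_{chrom}:{s1}-{e1}"

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    n_expression_filtered: int
    n_multi_detector: int
    n_known: int
    n_novel: int
    n_de_novo: int
    n_host_genes: int
    n_multi_isoform_genes: int
    hotspot_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.n_multi_detector <= self.n_expression_filtered <= self.n_total):
            raise ValueError("catalog counts violate filter ordering")


def _merge_key(iv: GenomicInterval, slack: int) -> tuple:
    if slack == 0:
        return (iv.chrom, iv.strand, iv.start, iv.end)
    return (iv.chrom, iv.strand, iv.start // (slack + 1), iv.end // (slack + 1))


def merge_bsj_calls(
    calls: Sequence[BsjCall],
    slack: int = 0,
    detector_priority: Sequence[str] = DEFAULT_DETECTOR_PRIORITY,
    count_mode: str = "max",
) -> list[CircRNA]:
    """Collapse per-detector BSJ calls into unified circRNA records.

    Calls merge when both BSJ coordinates agree within ``slack`` bases and the
    strand matches. Merged per-sample counts are the per-detector maximum
    (``count_mode="max"``, avoids double-counting the same reads) or mean.
    Output coordinates come from the first detector present in
    ``detector_priority``. Calls at identical coordinates but inconsistent
    strand are never merged; the records are flagged.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if count_mode not in ("max", "mean"):
        raise ValueError("count_mode must be 'max' or 'mean'")

    # Greedy clustering: sort by coordinates, open a new group when either end
    # drifts more than `slack` from the group representative.
    groups: dict[tuple, list[BsjCall]] = {}
    if slack == 0:
        for call in calls:
            groups.setdefault(_merge_key(call.interval, 0), []).append(call)
    else:
        reps: list[tuple[GenomicInterval, list[BsjCall]]] = []
        for call in sorted(calls, key=lambda c: (c.interval.chrom, c.interval.strand,
                                                 c.interval.start, c.interval.end)):
            iv = call.interval
            placed = False
            for rep, members in reps:
                if (
                    rep.chrom == iv.chrom
                    and rep.strand == iv.strand
                    and abs(rep.start - iv.start) <= slack
                    and abs(rep.end - iv.end) <= slack
                ):
                    members.append(call)
                    placed = True
                    break
            if not placed:
                reps.append((iv, [call]))
        groups = {i: members for i, (_, members) in enumerate(reps)}

    # flag strand conflicts: identical coordinates, opposite strand
    coord_strands: dict[tuple, set[str]] = {}
    for call in calls:
        iv = call.interval
        coord_strands.setdefault((iv.chrom, iv.start, iv.end), set()).add(iv.strand)

    rank = {d: i for i, d in enumerate(detector_priority)}
    out: list[CircRNA] = []
    for members in groups.values():
        members = sorted(members, key=lambda c: rank.get(c.detector_id, len(rank)))
        rep = members[0]
        counts = np.array([c.counts for c in members], dtype=float)
        if count_mode == "max":
            merged = counts.max(axis=0)
        else:
            merged = counts.mean(axis=0)
        iv = rep.interval
        conflict = len(coord_strands[(iv.chrom, iv.start, iv.end)]) > 1
        if conflict:
            logger.warning("strand conflict among detectors at %s:%d-%d",
                           iv.chrom, iv.start, iv.end)
        out.append(
            CircRNA(
                interval=iv,
                detectors=frozenset(c.detector_id for c in members),
                counts=tuple(int(round(v)) for v in merged),
                strand_conflict=conflict,
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end,
                            c.interval.strand))
    return out


def filter_expression(
    circs: Iterable[CircRNA], min_total_reads: int = 5, min_samples: int = 2
) -> list[CircRNA]:
    """Keep records with total merged reads >= ``min_total_reads`` and at least
    ``min_samples`` samples with >= 1 read."""
    if min_total_reads < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        c
        for c in circs
        if c.total_reads >= min_total_reads
        and sum(1 for v in c.counts if v >= 1) >= min_samples
    ]


def filter_detector_support(circs: Iterable[CircRNA], min_detectors: int = 2) -> list[CircRNA]:
    """Keep records detected by at least ``min_detectors`` programmes."""
    if min_detectors < 1:
        raise ValueError("min_detectors must be >= 1")
    return [c for c in circs if len(c.detectors) >= min_detectors]


def _boundary_indices(tx: TranscriptModel, circ_iv: GenomicInterval) -> Optional[tuple[int, int]]:
    i = next((k for k, e in enumerate(tx.exons) if e.start == circ_iv.start), None)
    j = next((k for k, e in enumerate(tx.exons) if e.end == circ_iv.end), None)
    if i is None or j is None or i > j:
        return None
    return (i, j)


def annotate_splice_status(
    circ: CircRNA,
    transcripts: Sequence[TranscriptModel],
    known_ids: Optional[Mapping[tuple[str, int, int, str], str]] = None,
) -> CircRNA:
    """Annotate a circRNA against transcript models and a known-circRNA lookup.

    ``annotation="annotated"`` iff both BSJ ends coincide exactly with exon
    boundaries of one transcript; the host gene, transcript and back-spliced
    exon indices are then assigned. Ambiguity across genes is resolved toward
    the longest transcript (warning logged). Otherwise the record stays
    ``de_novo`` with the host gene set by gene-span overlap when possible.
    ``known_ids`` maps ``(chrom, start, end, strand)`` (internal coordinates)
    to a circBase-style identifier.
    """
    iv = circ.interval
    candidates = []
    for tx in transcripts:
        if tx.chrom != iv.chrom or tx.strand != (iv.strand if iv.strand != "." else tx.strand):
            continue
        idx = _boundary_indices(tx, iv)
        if idx is not None:
            candidates.append((tx, idx))

    known = None
    if known_ids:
        known = known_ids.get((iv.chrom, iv.start, iv.end, iv.strand))

    if candidates:
        genes = {tx.gene_id for tx, _ in candidates}
        if len(genes) > 1:
            logger.warning(
                "BSJ %s:%d-%d matches exon boundaries in %d genes; "
                "resolving by longest transcript", iv.chrom, iv.start, iv.end, len(genes)
            )
        tx, idx = max(candidates, key=lambda c: (c[0].length, c[0].transcript_id))
        return replace(
            circ,
            annotation="annotated",
            host_gene=tx.gene_name,
            transcript_id=tx.transcript_id,
            bs_exon_indices=idx,
            known_id=known,
        )

    # de novo: host gene by span overlap if any, else intergenic
    host = "intergenic"
    for tx in transcripts:
        if tx.chrom == iv.chrom and tx.span.start < iv.end and iv.start < tx.span.end:
            host = tx.gene_name
            break
    return replace(circ, annotation="de_novo", host_gene=host,
                   transcript_id=None, bs_exon_indices=None, known_id=known)


def host_gene_summary(
    circs: Sequence[CircRNA],
    n_total: Optional[int] = None,
    n_expression_filtered: Optional[int] = None,
    hotspot_min: int = 11,
) -> CatalogSummary:
    """Summarise an annotated catalog.

    Hotspot genes host more than ten circRNAs (>= ``hotspot_min`` = 11);
    multi-isoform genes host two or more. ``n_total`` and
    ``n_expression_filtered`` default to ``len(circs)`` when upstream counts
    are not supplied.
    """
    n = len(circs)
    per_gene: dict[str, int] = {}
    for c in circs:
        if c.host_gene != "intergenic":
            per_gene[c.host_gene] = per_gene.get(c.host_gene, 0) + 1
    hotspots = tuple(sorted(g for g, k in per_gene.items() if k >= hotspot_min))
    return CatalogSummary(
        n_total=n if n_total is None else n_total,
        n_expression_filtered=n if n_expression_filtered is None else n_expression_filtered,
        n_multi_detector=n,
        n_known=sum(1 for c in circs if c.known_id is not None),
        n_novel=sum(1 for c in circs if c.annotation == "annotated" and c.known_id is None),
        n_de_novo=sum(1 for c in circs if c.annotation == "de_novo"),
        n_host_genes=len(per_gene),
        n_multi_isoform_genes=sum(1 for k in per_gene.values() if k >= 2),
        hotspot_genes=hotspots,
    )


def read_detector_table(
    path,
    detector_id: str,
    sample_columns: Sequence[str],
    coords: str = "bed",
) -> list[BsjCall]:
    """Read one detector's BSJ table (TSV with header).

    Required columns: ``chrom``, ``start``, ``end``, ``strand`` plus the
    per-sample count columns. ``coords="bed"`` means 0-based half-open on
    disk; ``coords="one_based"`` (CIRI-style) converts 1-based inclusive
    coordinates on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    offset = 1 if coords == "one_based" else 0
    calls = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start) - offset, int(row.end), row.strand)
        counts = tuple(int(getattr(row, c)) for c in sample_columns)
        calls.append(BsjCall(interval=iv, detector_id=detector_id, counts=counts))
    return calls


def catalog_to_frame(circs: Sequence[CircRNA], sample_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Catalog as a TSV-ready table (BED-style coordinates)."""
    rows = []
    for c in circs:
        row = {
            "circ_id": c.circ_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "host_gene": c.host_gene,
            "detectors": ",".join(sorted(c.detectors)),
            "n_detectors": len(c.detectors),
            "annotation": c.annotation,
            "known_id": c.known_id or "",
            "total_reads": c.total_reads,
        }
        names = sample_names or [f"sample_{i+1}" for i in range(len(c.counts))]
        row.update({name: v for name, v in zip(names, c.counts)})
        rows.append(row)
    return pd.DataFrame(rows)
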