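"""Flanking-intron extraction and inverted-Alu / intron-length classification.

For each annotated circRNA the two introns immediately adjacent to its
back-spliced exons are extracted (transcription orientation); Alu elements
retained by a 50%-overlap rule are assigned to each intron by proximity to
the BSJ; circRNAs whose two closest Alus sit on opposite strands carry
inverted Alu elements (IAE), and median splits on total flanking-intron
length and total BSJ-to-Alu distance define the four intron classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from circscape.catalog import CircRNA
from circscape.concordance import two_sample_z_test, ZTestResult
from circscape.intervals import (
    AluElement,
    GenomicInterval,
    TranscriptModel,
    anchor_distance,
    overlap_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FlankIntronPair",
    "IaeClassification",
    "MissingFlankingIntron",
    "INTRON_CLASSES",
    "extract_flanking_introns",
    "filter_alu_overlap",
    "closest_alu_pair",
    "classify_circ_introns",
    "intron_length_compare",
    "class_proportions",
]

INTRON_CLASSES = ("Short", "Long", "pIAE-short", "pIAE-long")


class MissingFlankingIntron(LookupError):
    """The circRNA lacks a flanking intron on at least one side."""


@dataclass(frozen=True)
class FlankIntronPair:
    """The two introns flanking a circRNA's back-spliced exons.

    ``upstream`` is 5' of the back-spliced acceptor exon in transcription
    orientation, ``downstream`` 3' of the donor exon.
    """

    circ_id: str
    upstream: GenomicInterval
    downstream: GenomicInterval
    strand: str

    @property
    def upstream_length(self) -> int:
        return len(self.upstream)

    @property
    def downstream_length(self) -> int:
        return len(self.downstream)

    @property
    def total_length(self) -> int:
        return len(self.upstream) + len(self.downstream)

    @property
    def bsj_anchor_upstream(self) -> int:
        """BSJ splice-site coordinate on the upstream intron's side."""
        # upstream intron abuts the acceptor exon: genomic left for +, right for -
        return self.upstream.end if self.strand != "-" else self.upstream.start

    @property
    def bsj_anchor_downstream(self) -> int:
        return self.downstream.start if self.strand != "-" else self.downstream.end


@dataclass(frozen=True)
class IaeClassification:
    circ_id: str
    dist_up: Optional[int]
    dist_down: Optional[int]
    inverted: Optional[bool]
    intron_class: str

    def __post_init__(self) -> None:
        if self.intron_class.startswith("pIAE") and not self.inverted:
            raise ValueError("pIAE classes require inverted Alu elements")

    @property
    def total_alu_distance(self) -> Optional[int]:
        if self.dist_up is None or self.dist_down is None:
            return None
        return self.dist_up + self.dist_down

    @property
    def has_iae(self) -> bool:
        return bool(self.inverted)


def extract_flanking_introns(circ: CircRNA, transcript: TranscriptModel) -> FlankIntronPair:
    """Introns immediately adjacent to the back-spliced exons.

    Raises :class:`MissingFlankingIntron` when a back-spliced exon is the
    transcript's first or last exon on the relevant side (no flanking intron
    exists); callers exclude and log such circRNAs.
    """
    if circ.bs_exon_indices is None:
        raise ValueError(f"{circ.circ_id} is not annotated to exons")
    i, j = circ.bs_exon_indices  # ascending genomic indices
    exons = transcript.exons
    if i == 0 or j == len(exons) - 1:
        raise MissingFlankingIntron(
            f"{circ.circ_id}: back-spliced exon at transcript boundary"
        )
    chrom = transcript.chrom
    left = GenomicInterval(chrom, exons[i - 1].end, exons[i].start, transcript.strand)
    right = GenomicInterval(chrom, exons[j].end, exons[j + 1].start, transcript.strand)
    if transcript.strand == "-":
        upstream, downstream = right, left
    else:
        upstream, downstream = left, right
    return FlankIntronPair(
        circ_id=circ.circ_id, upstream=upstream, downstream=downstream,
        strand=transcript.strand,
    )


def filter_alu_overlap(
    alus: Iterable[AluElement],
    introns: Sequence[GenomicInterval],
    min_fraction: float = 0.5,
) -> list[AluElement]:
    """Keep Alu elements overlapping any intron by at least ``min_fraction``
    of the element's own length (boundary inclusive)."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    out = []
    for alu in alus:
        best = max(
            (overlap_fraction(alu.interval, intron) for intron in introns
             if intron.chrom == alu.interval.chrom),
            default=0.0,
        )
        if best >= min_fraction:
            out.append(alu)
    return out


def _closest_in_intron(
    anchor: int, intron: GenomicInterval, alus: Sequence[AluElement]
) -> Optional[tuple[AluElement, int]]:
    best: Optional[tuple[int, int, int, AluElement]] = None
    for order, alu in enumerate(alus):
        iv = alu.interval
        if iv.chrom != intron.chrom:
            continue
        if min(iv.end, intron.end) - max(iv.start, intron.start) <= 0:
            continue
        d = anchor_distance(anchor, iv)
        key = (d, iv.start, order)
        if best is None or key < best[:3]:
            best = (d, iv.start, order, alu)
    if best is None:
        return None
    return best[3], best[0]


def closest_alu_pair(
    pair: FlankIntronPair, alus: Sequence[AluElement]
) -> tuple[Optional[int], Optional[int], Optional[bool]]:
    """Closest retained Alu to the BSJ in each flanking intron.

    Returns ``(dist_up, dist_down, inverted)``; distances are from the BSJ
    splice-site coordinate to the Alu's nearest edge (0 when the Alu overlaps
    or abuts the anchor). ``inverted`` is True when the two closest Alus sit
    on opposite strands, and ``None`` when either intron lacks a retained Alu
    (no IAE can be called).
    """
    up = _closest_in_intron(pair.bsj_anchor_upstream, pair.upstream, alus)
    down = _closest_in_intron(pair.bsj_anchor_downstream, pair.downstream, alus)
    dist_up = up[1] if up else None
    dist_down = down[1] if down else None
    inverted: Optional[bool] = None
    if up is not None and down is not None:
        inverted = up[0].strand != down[0].strand
    return dist_up, dist_down, inverted


def classify_circ_introns(
    pairs: Sequence[FlankIntronPair],
    iae_results: dict[str, tuple[Optional[int], Optional[int], Optional[bool]]],
) -> list[IaeClassification]:
    """Assign each circRNA one of Short / Long / pIAE-short / pIAE-long.

    The length median is computed over all circRNAs' total flanking-intron
    length; the distance median over the total BSJ-to-Alu distance of
    circRNAs carrying inverted Alus. Splits are strict (<): values equal to
    the median fall on the Long / non-proximal side.
    """
    if not pairs:
        raise ValueError("no flanking-intron pairs supplied")
    median_len = median(p.total_length for p in pairs)
    totals = []
    for p in pairs:
        du, dd, inv = iae_results.get(p.circ_id, (None, None, None))
        if inv and du is not None and dd is not None:
            totals.append(du + dd)
    median_dist = median(totals) if totals else None

    out = []
    for p in pairs:
        du, dd, inv = iae_results.get(p.circ_id, (None, None, None))
        short = p.total_length < median_len
        proximal = (
            bool(inv)
            and du is not None
            and dd is not None
            and median_dist is not None
            and (du + dd) < median_dist
        )
        if proximal:
            cls = "pIAE-short" if short else "pIAE-long"
        else:
            cls = "Short" if short else "Long"
        out.append(
            IaeClassification(
                circ_id=p.circ_id, dist_up=du, dist_down=dd,
                inverted=inv, intron_class=cls,
            )
        )
    return out


def class_proportions(classes: Sequence[IaeClassification]) -> pd.Series:
    """Proportion of each of the four intron classes (sums to 1)."""
    if not classes:
        raise ValueError("no classifications supplied")
    counts = pd.Series(0, index=list(INTRON_CLASSES), dtype=float)
    for c in classes:
        counts[c.intron_class] += 1
    return counts / counts.sum()


def intron_length_compare(
    subset_pairs: Sequence[FlankIntronPair],
    all_pairs: Sequence[FlankIntronPair],
    subset_classes: Optional[Sequence[IaeClassification]] = None,
    all_classes: Optional[Sequence[IaeClassification]] = None,
) -> dict:
    """Compare a circRNA subset's flanking-intron lengths against the cohort.

    Two-sample Z-test on total flanking-intron length (and, when
    classifications are supplied, on total Alu distance among IAE-carrying
    circRNAs), plus medians and per-set class-proportion tables.
    """
    if not subset_pairs:
        raise ValueError("subset is empty")
    subset_ids = {p.circ_id for p in subset_pairs}
    if not subset_ids <= {p.circ_id for p in all_pairs}:
        raise ValueError("subset must be contained in the full cohort")

    len_sub = [p.total_length for p in subset_pairs]
    len_all = [p.total_length for p in all_pairs]
    result: dict = {
        "length_test": two_sample_z_test(len_sub, len_all),
        "median_length_subset": median(len_sub),
        "median_length_all": median(len_all),
    }
    if subset_classes is not None and all_classes is not None:
        d_sub = [c.total_alu_distance for c in subset_classes
                 if c.has_iae and c.total_alu_distance is not None]
        d_all = [c.total_alu_distance for c in all_classes
                 if c.has_iae and c.total_alu_distance is not None]
        if len(d_sub) >= 2 and len(d_all) >= 2:
            result["distance_test"] = two_sample_z_test(d_sub, d_all)
            result["median_distance_subset"] = median(d_sub)
            result["median_distance_all"] = median(d_all)
        result["proportions_subset"] = class_proportions(subset_classes)
        result["proportions_all"] = class_proportions(all_classes)
    return result
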