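"""Coordinate conventions and genomic interval arithmetic.

Internal convention is 0-based half-open throughout; 1-based fully-closed
coordinates (GTF, user-facing circRNA IDs) are converted at the I/O boundary
by :func:`from_1based` / :func:`to_1based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "CoordinateError",
    "GenomicInterval",
    "TranscriptModel",
    "AluElement",
    "interval_length",
    "intervals_intersect",
    "overlap_bases",
    "overlap_fraction",
    "anchor_distance",
    "closest_feature",
    "from_1based",
    "to_1based",
    "parse_region_1based",
]


class CoordinateError(ValueError):
    """Raised for malformed coordinates or intervals."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based half-open span with ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Whether base offset ``pos`` lies within the interval."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons.

    Exons are stored in ascending genomic start order regardless of strand;
    all must share chromosome and strand and be pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise CoordinateError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in exons}
        if len(chroms) != 1:
            raise CoordinateError(
                f"transcript {self.transcript_id} exons span chromosomes {chroms}"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise CoordinateError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        """Summed exon length in bases."""
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Introns between consecutive exons, ascending genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class AluElement:
    """A repeat element from a RepeatMasker-style annotation."""

    interval: GenomicInterval
    family: str

    @property
    def strand(self) -> str:
        return self.interval.strand


def interval_length(iv: GenomicInterval) -> int:
    """Length of ``iv`` in bases (``end - start``)."""
    return iv.end - iv.start


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of overlapping bases between two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intervals_intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs ``(x, y, overlap)`` with ``x`` from ``a``, ``y`` from ``b``
    overlapping by at least one base.

    Half-open abutment does not count as overlap. Equivalent to an all-pairs
    scan; implemented as a per-chromosome sweep.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    out: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    import bisect

    for x in a:
        candidates = by_chrom.get(x.chrom, [])
        # candidates sorted by start; any with start >= x.end cannot overlap
        hi = bisect.bisect_left([c.start for c in candidates], x.end)
        for y in candidates[:hi]:
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((x, y, ov))
    return out


def overlap_fraction(feature: GenomicInterval, container: GenomicInterval) -> float:
    """Fraction of ``feature``'s length overlapped by ``container``, in [0, 1].

    Different chromosomes yield 0.0.
    """
    return overlap_bases(feature, container) / interval_length(feature)


def anchor_distance(anchor: int, feature: GenomicInterval) -> int:
    """Distance in bases from a junction coordinate ``anchor`` to ``feature``.

    The anchor is a splice-site coordinate (a cut point between bases): the
    distance is 0 whenever ``feature.start <= anchor <= feature.end`` — i.e. a
    feature overlapping or abutting the anchor is at distance 0, matching
    bedtools-closest semantics for bookended half-open intervals.
    """
    if anchor < feature.start:
        return feature.start - anchor
    if anchor > feature.end:
        return anchor - feature.end
    return 0


def closest_feature(
    anchor: int,
    features: Iterable[GenomicInterval],
    search_space: Optional[GenomicInterval] = None,
) -> Optional[tuple[GenomicInterval, int]]:
    """Closest feature to a junction coordinate, with its distance in bases.

    Ties are broken by smaller start coordinate, then by input order.
    ``search_space``, if given, restricts features to those overlapping it.
    Returns ``None`` for an empty feature set.
    """
    best: Optional[tuple[int, int, int, GenomicInterval]] = None
    for order, f in enumerate(features):
        if search_space is not None:
            if f.chrom != search_space.chrom or overlap_bases(f, search_space) == 0:
                continue
        d = anchor_distance(anchor, f)
        key = (d, f.start, order)
        if best is None or key < (best[0], best[1], best[2]):
            best = (d, f.start, order, f)
    if best is None:
        return None
    return best[3], best[0]


def from_1based(chrom: str, start1: int, end1: int, strand: str = ".") -> GenomicInterval:
    """Convert a 1-based fully-closed span to the internal convention."""
    return GenomicInterval(chrom, start1 - 1, end1, strand)


def to_1based(iv: GenomicInterval) -> tuple[str, int, int]:
    """Convert an internal interval to (chrom, start, end), 1-based inclusive."""
    return iv.chrom, iv.start + 1, iv.end


def parse_region_1based(region: str, strand: str = ".") -> GenomicInterval:
    """Parse ``chrom:start-end`` printed 1-based inclusive, e.g.
    ``chr6:73005640-73005667``."""
    try:
        chrom, span = region.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        return from_1based(chrom, int(lo), int(hi), strand)
    except (ValueError, CoordinateError) as exc:
        raise CoordinateError(f"cannot parse region {region!r}: {exc}") from exc
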