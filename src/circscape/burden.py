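"""Exon-class variant burden analysis.

Exons of the longest transcript containing the back-spliced exons are split
into circ/nonCirc groups, circ exons further into BSJ/nonBSJ, and variant
densities per Kb compared between groups with Z and Wilcoxon tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from circscape.catalog import CircRNA
from circscape.concordance import two_sample_z_test, wilcoxon_rank_sum, ZTestResult
from circscape.intervals import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExonClassRecord",
    "VariantRecord",
    "BurdenResult",
    "NoContainingTranscript",
    "select_longest_transcript",
    "classify_exons",
    "classify_exons_for_catalog",
    "deduplicate_exon_records",
    "tally_variants",
    "burden_compare",
    "impact_proportions",
    "missense_deleterious_fractions",
]

IMPACT_LEVELS = ("low", "medium", "high")
# most-circular-wins order used for de-duplicating shared exons
_CLASS_RANK = {"BSJ": 0, "nonBSJ": 1, "nonCirc": 2}


class NoContainingTranscript(LookupError):
    """No transcript's exon boundaries contain both BSJ ends."""


@dataclass(frozen=True)
class ExonClassRecord:
    exon: GenomicInterval
    transcript_id: str
    gene_id: str
    circ_class: str  # {"circ", "nonCirc"}
    bsj_class: str  # {"BSJ", "nonBSJ", "NA"}

    def __post_init__(self) -> None:
        if (self.bsj_class != "NA") != (self.circ_class == "circ"):
            raise ValueError("bsj_class must be NA exactly for nonCirc exons")

    @property
    def length_kb(self) -> float:
        return len(self.exon) / 1000.0

    @property
    def group_label(self) -> str:
        return self.bsj_class if self.circ_class == "circ" else "nonCirc"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based; indels anchored at their start position
    ref: str
    alt: str
    impact: str = "none"  # {"low", "medium", "high", "none"}
    flags: frozenset[str] = frozenset()  # subset of {missense, splice_region, deleterious}
    cohort: str = "gnomad"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("variant position must be >= 0")


@dataclass(frozen=True)
class BurdenResult:
    group_a: str
    group_b: str
    n_variants_a: int
    n_variants_b: int
    total_kb_a: float
    total_kb_b: float
    densities_a: tuple[float, ...]
    densities_b: tuple[float, ...]
    freq_per_kb_a: float
    freq_per_kb_b: float
    z: float
    p_z: float
    p_wilcoxon: float

    @property
    def pooled_ratio(self) -> float:
        """Pooled per-Kb frequency ratio a/b."""
        return self.freq_per_kb_a / self.freq_per_kb_b if self.freq_per_kb_b else np.inf

    @property
    def ztest(self) -> ZTestResult:
        return two_sample_z_test(self.densities_a, self.densities_b)


def select_longest_transcript(
    transcripts: Sequence[TranscriptModel], circ: CircRNA
) -> TranscriptModel:
    """Longest transcript whose exon boundaries contain both BSJ ends.

    Containment means some exon starts at the BSJ start and some exon ends at
    the BSJ end. Length is summed exon length; ties break lexicographically
    by transcript_id.
    """
    iv = circ.interval
    candidates = [
        tx
        for tx in transcripts
        if tx.chrom == iv.chrom
        and any(e.start == iv.start for e in tx.exons)
        and any(e.end == iv.end for e in tx.exons)
    ]
    if not candidates:
        raise NoContainingTranscript(
            f"no transcript contains both BSJ ends of {circ.circ_id}"
        )
    return min(candidates, key=lambda tx: (-tx.length, tx.transcript_id))


def classify_exons(transcript: TranscriptModel, circ: CircRNA) -> list[ExonClassRecord]:
    """Classify a transcript's exons relative to one circRNA.

    Exons between the back-spliced boundary exons (inclusive) are ``circ``;
    among those, the two boundary exons are ``BSJ`` and interior ones
    ``nonBSJ`` (no exon is assumed spliced out of the circRNA). All remaining
    exons are ``nonCirc``. A single-exon circRNA yields one BSJ exon.
    """
    iv = circ.interval
    i = next((k for k, e in enumerate(transcript.exons) if e.start == iv.start), None)
    j = next((k for k, e in enumerate(transcript.exons) if e.end == iv.end), None)
    if i is None or j is None or i > j:
        raise ValueError(
            f"transcript {transcript.transcript_id} does not contain the BSJ exons "
            f"of {circ.circ_id}"
        )
    out = []
    for k, exon in enumerate(transcript.exons):
        if i <= k <= j:
            circ_class = "circ"
            bsj_class = "BSJ" if k in (i, j) else "nonBSJ"
        else:
            circ_class, bsj_class = "nonCirc", "NA"
        out.append(
            ExonClassRecord(
                exon=exon,
                transcript_id=transcript.transcript_id,
                gene_id=transcript.gene_id,
                circ_class=circ_class,
                bsj_class=bsj_class,
            )
        )
    return out


def classify_exons_for_catalog(
    circs: Iterable[CircRNA],
    transcripts_by_gene: dict[str, list[TranscriptModel]],
    deduplicate: bool = True,
) -> list[ExonClassRecord]:
    """Exon classifications for every annotated circRNA in a catalog.

    circRNAs without a containing transcript are excluded and logged. A gene
    with several circRNAs contributes one classification per circRNA;
    duplicated (transcript, exon) records are collapsed keeping the most
    circular label (BSJ > nonBSJ > nonCirc) unless ``deduplicate=False``.
    """
    records: list[ExonClassRecord] = []
    for circ in circs:
        if circ.annotation != "annotated":
            continue
        gene_txs = transcripts_by_gene.get(circ.host_gene, [])
        try:
            tx = select_longest_transcript(gene_txs, circ)
        except NoContainingTranscript:
            logger.info("excluding %s: no containing transcript", circ.circ_id)
            continue
        records.extend(classify_exons(tx, circ))
    return deduplicate_exon_records(records) if deduplicate else records


def deduplicate_exon_records(records: Sequence[ExonClassRecord]) -> list[ExonClassRecord]:
    """Collapse duplicate (transcript, exon) records to the most circular label."""
    best: dict[tuple, ExonClassRecord] = {}
    for rec in records:
        key = (rec.transcript_id, rec.exon.chrom, rec.exon.start, rec.exon.end)
        cur = best.get(key)
        if cur is None or _CLASS_RANK[rec.group_label] < _CLASS_RANK[cur.group_label]:
            best[key] = rec
    return sorted(
        best.values(), key=lambda r: (r.exon.chrom, r.exon.start, r.exon.end, r.transcript_id)
    )


def tally_variants(
    exons: Sequence[ExonClassRecord], variants: Sequence[VariantRecord]
) -> pd.DataFrame:
    """Per-exon variant counts and per-Kb densities.

    A variant belongs to an exon when its (0-based) position lies inside the
    half-open exon span; a position at the exon end boundary is outside.
    """
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    sorted_pos = {c: np.sort(np.array(p, dtype=int)) for c, p in by_chrom.items()}
    rows = []
    for rec in exons:
        pos = sorted_pos.get(rec.exon.chrom)
        if pos is None:
            count = 0
        else:
            count = int(
                np.searchsorted(pos, rec.exon.end, side="left")
                - np.searchsorted(pos, rec.exon.start, side="left")
            )
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "gene_id": rec.gene_id,
                "chrom": rec.exon.chrom,
                "start": rec.exon.start,
                "end": rec.exon.end,
                "circ_class": rec.circ_class,
                "bsj_class": rec.bsj_class,
                "group": rec.group_label,
                "length_kb": rec.length_kb,
                "n_variants": count,
                "density_per_kb": count / rec.length_kb,
            }
        )
    return pd.DataFrame(rows)


def _filter_variants(
    variants: Sequence[VariantRecord],
    flag: Optional[str] = None,
    impacts: Optional[set[str]] = None,
    cohort: Optional[str] = None,
) -> list[VariantRecord]:
    out = list(variants)
    if cohort is not None:
        out = [v for v in out if v.cohort == cohort]
    if flag is not None:
        out = [v for v in out if flag in v.flags]
    if impacts is not None:
        out = [v for v in out if v.impact in impacts]
    return out


def burden_compare(
    exons: Sequence[ExonClassRecord],
    variants: Sequence[VariantRecord],
    grouping: str = "circ",
    flag: Optional[str] = None,
    impacts: Optional[set[str]] = None,
    cohort: Optional[str] = None,
) -> BurdenResult:
    """Compare per-Kb variant density between two exon groups.

    ``grouping="circ"`` compares circ vs nonCirc exons; ``grouping="bsj"``
    compares BSJ vs nonBSJ exons (within circ exons). Optional filters select
    a variant flag (e.g. ``splice_region``), impact subset or cohort before
    tallying. Per-exon density vectors feed the two-sample Z-test and
    Wilcoxon rank-sum; pooled per-Kb frequencies are reported alongside.
    """
    if grouping == "circ":
        group_a, group_b = "circ", "nonCirc"
        key = "circ_class"
    elif grouping == "bsj":
        group_a, group_b = "BSJ", "nonBSJ"
        key = "bsj_class"
    else:
        raise ValueError("grouping must be 'circ' or 'bsj'")

    filtered = _filter_variants(variants, flag=flag, impacts=impacts, cohort=cohort)
    table = tally_variants(exons, filtered)
    sub_a = table[table[key] == group_a]
    sub_b = table[table[key] == group_b]
    for label, sub in ((group_a, sub_a), (group_b, sub_b)):
        if sub.empty:
            raise ValueError(f"group {label!r} is empty after filtering")

    dens_a = sub_a["density_per_kb"].to_numpy()
    dens_b = sub_b["density_per_kb"].to_numpy()
    zres = two_sample_z_test(dens_a, dens_b)
    _, p_w = wilcoxon_rank_sum(dens_a, dens_b)
    kb_a = float(sub_a["length_kb"].sum())
    kb_b = float(sub_b["length_kb"].sum())
    n_a = int(sub_a["n_variants"].sum())
    n_b = int(sub_b["n_variants"].sum())
    return BurdenResult(
        group_a=group_a,
        group_b=group_b,
        n_variants_a=n_a,
        n_variants_b=n_b,
        total_kb_a=kb_a,
        total_kb_b=kb_b,
        densities_a=tuple(dens_a),
        densities_b=tuple(dens_b),
        freq_per_kb_a=n_a / kb_a,
        freq_per_kb_b=n_b / kb_b,
        z=zres.z,
        p_z=zres.p,
        p_wilcoxon=p_w,
    )


def impact_proportions(variants_by_group: dict[str, Sequence[VariantRecord]]) -> pd.DataFrame:
    """Per-group proportions of low/medium/high impact variants.

    Variants with ``impact="none"`` are excluded (their count is reported in
    the ``n_unscored`` column); proportions sum to 1 per group.
    """
    rows = []
    for group, variants in variants_by_group.items():
        scored = [v for v in variants if v.impact in IMPACT_LEVELS]
        if not scored:
            raise ValueError(f"group {group!r} has no impact-scored variants")
        n = len(scored)
        row = {"group": group, "n_scored": n,
               "n_unscored": len(variants) - n}
        for level in IMPACT_LEVELS:
            row[level] = sum(1 for v in scored if v.impact == level) / n
        rows.append(row)
    return pd.DataFrame(rows)


def missense_deleterious_fractions(
    variants: Sequence[VariantRecord],
) -> tuple[float, Optional[float]]:
    """(fraction missense, fraction of missense flagged deleterious).

    The second fraction is conditional on missense and ``None`` when there
    are no missense variants.
    """
    if not variants:
        raise ValueError("no variants supplied")
    missense = [v for v in variants if "missense" in v.flags]
    frac_mis = len(missense) / len(variants)
    if not missense:
        return frac_mis, None
    frac_del = sum(1 for v in missense if "deleterious" in v.flags) / len(missense)
    return frac_mis, frac_del
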