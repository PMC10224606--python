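"""End-to-end orchestration of the analysis stages on file inputs.

Stages run in dependency order (catalog -> concordance -> burden -> motifs ->
introns -> axes); every threshold used is echoed into the JSON summary, and a
rerun on identical inputs is bit-identical apart from nothing — no timestamps
are written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from circscape import io as cio
from circscape.axes import MirnaSite, axes_to_frame, build_axes
from circscape.burden import (
    VariantRecord,
    burden_compare,
    classify_exons_for_catalog,
)
from circscape.catalog import (
    annotate_splice_status,
    catalog_to_frame,
    filter_detector_support,
    filter_expression,
    host_gene_summary,
    merge_bsj_calls,
    read_detector_table,
)
from circscape.concordance import classify_de, fold_ratio_stats, lfc_correlation
from circscape.introns import (
    MissingFlankingIntron,
    classify_circ_introns,
    closest_alu_pair,
    extract_flanking_introns,
    filter_alu_overlap,
    class_proportions,
)
from circscape.motifs import (
    extract_interval_sequence,
    positional_profile,
    read_consensus_motifs,
    scan_sequences,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("catalog", "concordance", "burden", "motifs", "introns", "axes")

_KNOWN_KEYS = {
    "gtf", "genome", "detector_tables", "sample_columns", "de_circ", "de_linear",
    "variants", "repeats", "motifs", "mirna_sites", "stages", "outdir", "seed",
    "min_total_reads", "min_samples", "min_detectors", "merge_slack",
    "lfc_threshold", "padj_threshold", "motif_p_threshold", "alu_min_fraction",
    "profile_bin_width", "profile_anchor",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed)."""

    outdir: str
    gtf: Optional[str] = None
    genome: Optional[str] = None
    detector_tables: list = field(default_factory=list)  # {path, detector_id, coords}
    sample_columns: list = field(default_factory=list)
    de_circ: Optional[str] = None
    de_linear: Optional[str] = None
    variants: Optional[str] = None
    repeats: Optional[str] = None
    motifs: Optional[str] = None
    mirna_sites: Optional[str] = None
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    min_total_reads: int = 5
    min_samples: int = 2
    min_detectors: int = 2
    merge_slack: int = 0
    lfc_threshold: float = 2.0
    padj_threshold: float = 0.05
    motif_p_threshold: float = 0.001
    alu_min_fraction: float = 0.5
    profile_bin_width: int = 100
    profile_anchor: str = "five_prime_end"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for key in ("gtf", "genome", "de_circ", "de_linear", "variants",
                    "repeats", "motifs", "mirna_sites"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")
        for entry in self.detector_tables:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(f"detector table {entry['path']} does not exist")


def _read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        flags = frozenset(str(row.flags).split(",")) if isinstance(row.flags, str) and row.flags else frozenset()
        out.append(
            VariantRecord(chrom=row.chrom, pos=int(row.pos0), ref=row.ref,
                          alt=row.alt, impact=row.impact, flags=flags,
                          cohort=row.cohort)
        )
    return out


def _read_sites(path) -> tuple[list[MirnaSite], list[MirnaSite]]:
    df = pd.read_csv(path, sep="\t")
    circ, utr = [], []
    for row in df.itertuples(index=False):
        site = MirnaSite(mirna=row.mirna, target_id=row.target_id,
                         target_type=row.target_type, position=int(row.position),
                         n_sites=int(row.n_sites),
                         method=getattr(row, "method", "external"))
        (circ if site.target_type == "circ" else utr).append(site)
    return circ, utr


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; write TSV outputs plus ``summary.json``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("circscape")
    root.addHandler(handler)

    summary: dict = {
        "thresholds": {
            "min_total_reads": config.min_total_reads,
            "min_samples": config.min_samples,
            "min_detectors": config.min_detectors,
            "merge_slack": config.merge_slack,
            "lfc_threshold": config.lfc_threshold,
            "padj_threshold": config.padj_threshold,
            "motif_p_threshold": config.motif_p_threshold,
            "alu_min_fraction": config.alu_min_fraction,
            "profile_bin_width": config.profile_bin_width,
        },
        "stages_run": list(config.stages),
        "seed": config.seed,
    }

    transcripts = cio.read_gtf(config.gtf) if config.gtf else []
    tx_by_gene: dict[str, list] = {}
    for tx in transcripts:
        tx_by_gene.setdefault(tx.gene_name, []).append(tx)
    genome = cio.read_fasta(config.genome) if config.genome else {}

    catalog = []
    try:
        if "catalog" in config.stages:
            calls = []
            for entry in config.detector_tables:
                calls.extend(
                    read_detector_table(entry["path"], entry["detector_id"],
                                        config.sample_columns,
                                        coords=entry.get("coords", "bed"))
                )
            merged = merge_bsj_calls(calls, slack=config.merge_slack)
            expressed = filter_expression(merged, config.min_total_reads, config.min_samples)
            supported = filter_detector_support(expressed, config.min_detectors)
            catalog = [annotate_splice_status(c, transcripts) for c in supported]
            cat_summary = host_gene_summary(
                catalog, n_total=len(merged), n_expression_filtered=len(expressed))
            cio.write_tsv(catalog_to_frame(catalog), outdir / "catalog.tsv")
            summary["catalog"] = {
                **{k: getattr(cat_summary, k) for k in
                   ("n_total", "n_expression_filtered", "n_multi_detector", "n_known",
                    "n_novel", "n_de_novo", "n_host_genes", "n_multi_isoform_genes")},
                "hotspot_genes": list(cat_summary.hotspot_genes),
            }
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise PipelineError("catalog", exc) from exc

    circ_de = cio.read_tsv(config.de_circ) if config.de_circ else None
    lin_de = cio.read_tsv(config.de_linear) if config.de_linear else None
    circ_labels: dict[str, str] = {}
    mrna_labels: dict[str, str] = {}

    try:
        if "concordance" in config.stages and circ_de is not None and lin_de is not None:
            circ_lab = classify_de(circ_de, config.lfc_threshold, config.padj_threshold)
            lin_lab = classify_de(lin_de, config.lfc_threshold, config.padj_threshold)
            circ_labels = dict(zip(circ_de["feature_id"], circ_lab))
            mrna_labels = dict(zip(lin_de["feature_id"], lin_lab))
            pairing = {cid: cid.rsplit("_", 1)[0] for cid in circ_de["feature_id"]}
            r, p, n_pairs = lfc_correlation(circ_de, lin_de, pairing)
            circ_lfc = circ_de.set_index("feature_id")["lfc"]
            lin_lfc = lin_de.set_index("feature_id")["lfc"]
            pairs = [
                (float(circ_lfc[c]), float(lin_lfc[h]))
                for c, h in pairing.items() if h in lin_lfc.index
            ]
            frac, mean_fold = fold_ratio_stats(pairs, margin_log2=1.0, top_n=20)
            summary["concordance"] = {
                "pearson_r": r, "p": p, "n_pairs": n_pairs,
                "fraction_over_twofold": frac, "mean_fold_excess_top20": mean_fold,
                "n_up": int((circ_lab == "up").sum()),
                "n_down": int((circ_lab == "down").sum()),
            }
    except Exception as exc:
        raise PipelineError("concordance", exc) from exc

    exon_records = []
    try:
        if "burden" in config.stages and config.variants:
            variants = _read_variants(config.variants)
            exon_records = classify_exons_for_catalog(catalog, tx_by_gene)
            results = {}
            for grouping in ("circ", "bsj"):
                res = burden_compare(exon_records, variants, grouping=grouping)
                results[grouping] = {
                    "freq_per_kb_a": res.freq_per_kb_a,
                    "freq_per_kb_b": res.freq_per_kb_b,
                    "z": res.z, "p_z": res.p_z, "p_wilcoxon": res.p_wilcoxon,
                }
            summary["burden"] = results
    except Exception as exc:
        raise PipelineError("burden", exc) from exc

    pairs_by_id = {}
    flank_pairs = []
    try:
        if "introns" in config.stages and config.repeats and catalog:
            tx_by_id = {tx.transcript_id: tx for tx in transcripts}
            for circ in catalog:
                if circ.transcript_id is None:
                    continue
                try:
                    pair = extract_flanking_introns(circ, tx_by_id[circ.transcript_id])
                except MissingFlankingIntron:
                    logger.info("no flanking introns for %s", circ.circ_id)
                    continue
                flank_pairs.append(pair)
                pairs_by_id[pair.circ_id] = pair
            alus = cio.read_repeats(config.repeats, family_prefix="Alu")
            introns = [p.upstream for p in flank_pairs] + [p.downstream for p in flank_pairs]
            retained = filter_alu_overlap(alus, introns, config.alu_min_fraction)
            iae = {p.circ_id: closest_alu_pair(p, retained) for p in flank_pairs}
            classes = classify_circ_introns(flank_pairs, iae)
            cio.write_tsv(
                pd.DataFrame(
                    [{"circ_id": c.circ_id, "dist_up": c.dist_up,
                      "dist_down": c.dist_down, "inverted": c.inverted,
                      "intron_class": c.intron_class} for c in classes]
                ),
                outdir / "intron_classes.tsv",
            )
            summary["introns"] = {
                "n_with_flanking_introns": len(flank_pairs),
                "class_proportions": class_proportions(classes).to_dict(),
            }
    except Exception as exc:
        raise PipelineError("introns", exc) from exc

    try:
        if "motifs" in config.stages and config.motifs and genome and flank_pairs:
            motifs = read_consensus_motifs(config.motifs)
            intron_seqs = {}
            intron_info = {}
            for pair in flank_pairs:
                for side, iv in (("upstream", pair.upstream), ("downstream", pair.downstream)):
                    sid = f"{pair.circ_id}|{side}"
                    intron_seqs[sid] = extract_interval_sequence(iv, genome, pair.strand)
                    intron_info[sid] = (len(iv), side)
            hits = scan_sequences(intron_seqs, motifs, config.motif_p_threshold)
            profile = positional_profile(
                hits, intron_info, anchor=config.profile_anchor,
                bin_width=config.profile_bin_width, normaliser=max(1, len(flank_pairs)))
            cio.write_tsv(
                pd.DataFrame(
                    [{"motif": h.motif_name, "sequence_id": h.sequence_id,
                      "offset": h.offset, "score": h.score, "p": h.p} for h in hits]
                ),
                outdir / "motif_hits.tsv",
            )
            summary["motifs"] = {
                "n_hits": len(hits),
                "profile_anchor": profile.anchor,
                "profile_frequencies": list(profile.frequencies),
            }
    except Exception as exc:
        raise PipelineError("motifs", exc) from exc

    try:
        if "axes" in config.stages and config.mirna_sites and circ_labels:
            circ_sites, utr_sites = _read_sites(config.mirna_sites)
            axes, max_sites = build_axes(circ_sites, utr_sites, circ_labels, mrna_labels)
            cio.write_tsv(axes_to_frame(axes), outdir / "axes.tsv")
            summary["axes"] = {"n_axes": len(axes), "max_sites_per_circ": max_sites}
    except Exception as exc:
        raise PipelineError("axes", exc) from exc

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    root.removeHandler(handler)
    handler.close()
    return summary
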