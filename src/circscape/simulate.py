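"""Seeded generators for every input the pipeline consumes.

Each generator plants a recoverable effect (detector concordance, circ/linear
LFC correlation and offset, circ-exon variant density ratio, inverted-Alu
pairs at controlled distances, 5'-biased motif positions, miRNA seed sites)
and emits a machine-readable truth table so downstream recovery can be
scored. All randomness flows from ``SynthConfig.seed`` through per-stage
`numpy` generators: a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from circscape.axes import MirnaSite, seed_match_sites
from circscape.burden import ExonClassRecord, VariantRecord
from circscape.catalog import BsjCall, CircRNA
from circscape.intervals import AluElement, GenomicInterval, TranscriptModel
from circscape.introns import FlankIntronPair
from circscape.motifs import revcomp_rna, rna

__all__ = [
    "SynthConfig",
    "generate_genome",
    "generate_true_circs",
    "generate_bsj_calls",
    "generate_de_tables",
    "generate_variants",
    "generate_alu_annotation",
    "plant_motifs",
    "generate_mirna_sites",
    "simulate_all",
]

DETECTORS = ("circexplorer2", "ciri2", "mapsplice")

# stage tags keep per-stage RNG streams independent of call order
_STAGE = {
    "genome": 1,
    "circs": 2,
    "bsj": 3,
    "de": 4,
    "variants": 5,
    "alu": 6,
    "motifs": 7,
    "mirna": 8,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort; all planted effects live here."""

    seed: int = 0
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (400, 3000)
    intergenic_gap: int = 300
    n_samples: int = 8
    detector_concordance: float = 0.9
    false_bsj_rate: float = 0.0
    circ_fraction: float = 0.8
    two_isoform_prob: float = 0.2
    nb_mean: float = 20.0
    nb_dispersion: float = 0.5
    lfc_rho: float = 0.5
    lfc_offset: float = 1.0
    lfc_sd: float = 1.5
    variant_density_per_kb: float = 10.0
    variant_density_ratio: float = 2.0
    alu_length: int = 120
    planted_iae_fraction: float = 0.5
    iae_distance_range: tuple[int, int] = (0, 200)
    motif_5prime_bias: float = 0.01  # geometric decay; 0 = uniform placement
    motifs_per_sequence: float = 3.0
    mirna_panel: int = 10
    mirna_target_prob: float = 0.3

    def __post_init__(self) -> None:
        for name in ("detector_concordance", "false_bsj_rate", "circ_fraction",
                     "two_isoform_prob", "planted_iae_fraction", "mirna_target_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exons_per_gene[0] < 4:
            raise ValueError("genes need >= 4 exons so circRNAs keep flanking introns")
        if self.intron_length[0] <= self.alu_length:
            raise ValueError("introns must be longer than an Alu element")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_genome(config: SynthConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """A synthetic chromosome with multi-exon genes on alternating strands."""
    rng = config.rng("genome")
    transcripts = []
    cursor = config.intergenic_gap
    chrom = "chrS"
    for g in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if g % 2 == 0 else "-"
        exons = []
        pos = cursor
        for k in range(n_ex):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if k < n_ex - 1:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{g:04d}",
                gene_id=f"G{g:04d}",
                gene_name=f"GENE{g:04d}",
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursor = pos + config.intergenic_gap
    genome = {chrom: _rand_seq(rng, cursor + config.intergenic_gap)}
    return genome, transcripts


def generate_true_circs(
    config: SynthConfig, transcripts: Sequence[TranscriptModel]
) -> list[CircRNA]:
    """Ground-truth circRNAs over interior exons (flanking introns exist)."""
    rng = config.rng("circs")
    circs = []
    for tx in transcripts:
        if rng.random() >= config.circ_fraction:
            continue
        n_ex = len(tx.exons)
        n_iso = 2 if rng.random() < config.two_isoform_prob else 1
        spans = set()
        for _ in range(n_iso):
            i = int(rng.integers(1, n_ex - 1))
            j = int(rng.integers(i, n_ex - 1))
            spans.add((i, j))
        for i, j in sorted(spans):
            iv = GenomicInterval(tx.chrom, tx.exons[i].start, tx.exons[j].end, tx.strand)
            circs.append(
                CircRNA(
                    interval=iv,
                    detectors=frozenset({"truth"}),
                    counts=(),
                    host_gene=tx.gene_name,
                    annotation="annotated",
                    transcript_id=tx.transcript_id,
                    bs_exon_indices=(i, j),
                )
            )
    return circs


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def generate_bsj_calls(
    config: SynthConfig, truth: Sequence[CircRNA]
) -> tuple[dict[str, list[BsjCall]], pd.DataFrame]:
    """Three pseudo-detector call sets plus a truth table.

    Each true circRNA is reported by each detector independently with
    probability ``detector_concordance``; counts are negative binomial.
    Detector-specific false BSJs are added at ``false_bsj_rate`` x truth size
    per detector, at coordinates disjoint from the truth set.
    """
    rng = config.rng("bsj")
    calls: dict[str, list[BsjCall]] = {d: [] for d in DETECTORS}
    rows = []
    truth_keys = {
        (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand)
        for c in truth
    }
    for circ in truth:
        reported = []
        base = _nb_counts(rng, config.nb_mean, config.nb_dispersion, config.n_samples)
        for det in DETECTORS:
            if rng.random() < config.detector_concordance:
                # detectors see the same library; per-detector jitter on counts
                noise = rng.integers(0, 3, size=config.n_samples)
                counts = np.maximum(base - noise, 0)
                calls[det].append(
                    BsjCall(interval=circ.interval, detector_id=det,
                            counts=tuple(int(v) for v in counts))
                )
                reported.append(det)
        rows.append(
            {
                "circ_id": circ.circ_id,
                "chrom": circ.interval.chrom,
                "start": circ.interval.start,
                "end": circ.interval.end,
                "strand": circ.interval.strand,
                "detectors": ",".join(reported),
                "n_detectors": len(reported),
            }
        )
    n_false = int(round(config.false_bsj_rate * len(truth)))
    for det in DETECTORS:
        for _ in range(n_false):
            while True:
                start = int(rng.integers(0, 10_000_000))
                end = start + int(rng.integers(200, 2000))
                if ("chrS", start, end, "+") not in truth_keys:
                    break
            counts = _nb_counts(rng, config.nb_mean, config.nb_dispersion, config.n_samples)
            calls[det].append(
                BsjCall(
                    interval=GenomicInterval("chrS", start, end, "+"),
                    detector_id=det,
                    counts=tuple(int(v) for v in counts),
                )
            )
    return calls, pd.DataFrame(rows)


def generate_de_tables(
    config: SynthConfig, truth: Sequence[CircRNA]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Differential-expression tables with planted circ/linear concordance.

    Per host gene a linear LFC is drawn N(0, lfc_sd^2); each of its circRNAs
    gets ``lfc_offset + rho * lfc_linear + lfc_sd * sqrt(1 - rho^2) * eps``,
    so the population circ/linear correlation is exactly ``lfc_rho`` and the
    mean circ excess is ``lfc_offset``. padj comes from simulated Wald
    p-values with Benjamini-Hochberg adjustment per table.
    """
    rng = config.rng("de")
    rho, sd = config.lfc_rho, config.lfc_sd
    genes = sorted({c.host_gene for c in truth})
    lin_lfc = {g: float(rng.normal(0.0, sd)) for g in genes}

    def padj_from_lfc(lfcs: np.ndarray, se: float = 0.5) -> np.ndarray:
        p = 2.0 * stats.norm.sf(np.abs(lfcs) / se)
        return stats.false_discovery_control(p, method="bh")

    circ_rows, pairing = [], {}
    circ_lfcs = []
    for c in truth:
        eps = float(rng.normal())
        lfc = config.lfc_offset + rho * lin_lfc[c.host_gene] + sd * np.sqrt(1 - rho**2) * eps
        circ_lfcs.append(lfc)
        pairing[c.circ_id] = c.host_gene
        circ_rows.append(
            {"feature_id": c.circ_id, "base_mean": float(rng.lognormal(3.0, 1.0)),
             "lfc": lfc}
        )
    circ_df = pd.DataFrame(circ_rows)
    circ_df["padj"] = padj_from_lfc(circ_df["lfc"].to_numpy())

    lin_df = pd.DataFrame(
        [
            {"feature_id": g, "base_mean": float(rng.lognormal(5.0, 1.0)),
             "lfc": lin_lfc[g]}
            for g in genes
        ]
    )
    lin_df["padj"] = padj_from_lfc(lin_df["lfc"].to_numpy())
    return circ_df, lin_df, pairing


def generate_variants(
    config: SynthConfig, exons: Sequence[ExonClassRecord], cohort: str = "gnomad"
) -> list[VariantRecord]:
    """Poisson variant placement with a planted circ/nonCirc density ratio.

    nonCirc exons receive density d = ``variant_density_per_kb``; circ exons
    receive ``variant_density_ratio * d``. Impact and flags are categorical.
    """
    rng = config.rng("variants")
    bases = np.array(list("ACGT"))
    out = []
    for rec in exons:
        d = config.variant_density_per_kb
        if rec.circ_class == "circ":
            d *= config.variant_density_ratio
        n = int(rng.poisson(d * rec.length_kb))
        if n == 0:
            continue
        positions = rng.integers(rec.exon.start, rec.exon.end, size=n)
        for pos in positions:
            impact = str(rng.choice(["low", "medium", "high"], p=[0.5, 0.3, 0.2]))
            flags = set()
            if rng.random() < 0.3:
                flags.add("missense")
                if rng.random() < 0.4:
                    flags.add("deleterious")
            if rng.random() < 0.15:
                flags.add("splice_region")
            ref, alt = rng.choice(bases, size=2, replace=False)
            out.append(
                VariantRecord(chrom=rec.exon.chrom, pos=int(pos), ref=str(ref),
                              alt=str(alt), impact=impact,
                              flags=frozenset(flags), cohort=cohort)
            )
    return out


def _place_alu(
    intron: GenomicInterval, anchor: int, dist: int, length: int, strand: str
) -> AluElement:
    """Place an Alu fully inside ``intron`` with its BSJ-near edge ``dist``
    bases from the splice-site anchor (clamped to fit)."""
    max_dist = len(intron) - length
    d = min(dist, max(0, max_dist))
    if anchor == intron.end:  # intron genomically left of the BSJ
        iv = GenomicInterval(intron.chrom, anchor - d - length, anchor - d, strand)
    else:  # anchor == intron.start
        iv = GenomicInterval(intron.chrom, anchor + d, anchor + d + length, strand)
    return AluElement(interval=iv, family="AluY")


def generate_alu_annotation(
    config: SynthConfig, pairs: Sequence[FlankIntronPair]
) -> tuple[list[AluElement], pd.DataFrame]:
    """Repeat annotation with inverted-Alu pairs planted at controlled
    distances for ``planted_iae_fraction`` of circRNAs.

    Remaining circRNAs get same-strand Alus in both introns (half) or none.
    """
    rng = config.rng("alu")
    lo, hi = config.iae_distance_range
    alus: list[AluElement] = []
    rows = []
    for pair in pairs:
        u = rng.random()
        d_up = int(rng.integers(lo, hi + 1))
        d_down = int(rng.integers(lo, hi + 1))
        if u < config.planted_iae_fraction:
            kind = "iae"
            strands = ("+", "-") if rng.random() < 0.5 else ("-", "+")
        elif u < config.planted_iae_fraction + (1 - config.planted_iae_fraction) / 2:
            kind = "same"
            strands = ("+", "+")
        else:
            kind = "none"
            strands = None
        if strands is not None:
            alus.append(_place_alu(pair.upstream, pair.bsj_anchor_upstream,
                                   d_up, config.alu_length, strands[0]))
            alus.append(_place_alu(pair.downstream, pair.bsj_anchor_downstream,
                                   d_down, config.alu_length, strands[1]))
        rows.append(
            {"circ_id": pair.circ_id, "planted": kind,
             "dist_up": d_up if strands else -1,
             "dist_down": d_down if strands else -1}
        )
    return alus, pd.DataFrame(rows)


def plant_motifs(
    config: SynthConfig,
    sequences: Mapping[str, str],
    consensus: str = "UGUGUGA",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Overwrite motif instances into sequences with a 5'-biased position law.

    Offsets are geometric(``motif_5prime_bias``) from the 5' end (uniform when
    the bias is 0); instances never overlap each other, so an exact-consensus
    scan recovers every planted offset. Returns mutated copies plus the truth
    table of planted positions.
    """
    rng = config.rng("motifs")
    consensus = rna(consensus)
    L = len(consensus)
    mutated = {}
    rows = []
    for seq_id in sorted(sequences):
        seq = list(rna(sequences[seq_id]))
        n = int(rng.poisson(config.motifs_per_sequence))
        taken: list[tuple[int, int]] = []
        for _ in range(n):
            if config.motif_5prime_bias > 0:
                off = int(rng.geometric(config.motif_5prime_bias)) - 1
            else:
                off = int(rng.integers(0, max(1, len(seq) - L)))
            if off > len(seq) - L:
                continue
            if any(not (off + L <= s or off >= e) for s, e in taken):
                continue
            seq[off : off + L] = consensus
            taken.append((off, off + L))
            rows.append({"sequence_id": seq_id, "offset": off, "consensus": consensus})
        mutated[seq_id] = "".join(seq)
    return mutated, pd.DataFrame(rows, columns=["sequence_id", "offset", "consensus"])


def generate_mirna_sites(
    config: SynthConfig,
    circ_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, str], list[MirnaSite], list[MirnaSite], pd.DataFrame]:
    """Plant miRNA seed complements into circRNA and 3'UTR sequences.

    Each miRNA of the panel targets each circRNA / UTR independently with
    probability ``mirna_target_prob``; planted targets receive 1-3 seed
    sites. Site tables are then derived by seed matching on the mutated
    sequences, and the truth table lists every planted (mirna, target).
    """
    rng = config.rng("mirna")
    mirnas = {f"miR-S{i+1}": _rand_seq(rng, 21).replace("T", "U")
              for i in range(config.mirna_panel)}
    circ_out = {k: rna(v) for k, v in circ_seqs.items()}
    utr_out = {k: rna(v) for k, v in utr_seqs.items()}
    rows = []

    def plant(target_map: dict[str, str], target_type: str) -> None:
        for target_id in sorted(target_map):
            for name, mseq in mirnas.items():
                if rng.random() >= config.mirna_target_prob:
                    continue
                site = revcomp_rna(mseq[1:8])
                seq = list(target_map[target_id])
                k = len(site)
                n_plant = int(rng.integers(1, 4))
                planted = 0
                for _ in range(n_plant):
                    if len(seq) <= k:
                        break
                    off = int(rng.integers(0, len(seq) - k))
                    seq[off : off + k] = site
                    planted += 1
                target_map[target_id] = "".join(seq)
                if planted:
                    rows.append({"mirna": name, "target_id": target_id,
                                 "target_type": target_type, "n_planted": planted})

    plant(circ_out, "circ")
    plant(utr_out, "utr3")

    circ_sites = [
        s for target_id, seq in sorted(circ_out.items())
        for name, mseq in mirnas.items()
        if (s := seed_match_sites(seq, name, mseq, target_id, "circ")) is not None
    ]
    utr_sites = [
        s for target_id, seq in sorted(utr_out.items())
        for name, mseq in mirnas.items()
        if (s := seed_match_sites(seq, name, mseq, target_id, "utr3")) is not None
    ]
    truth = pd.DataFrame(rows, columns=["mirna", "target_id", "target_type", "n_planted"])
    return circ_out, utr_out, circ_sites, utr_sites, truth


def simulate_all(config: SynthConfig, outdir) -> dict:
    """Generate and write the full synthetic input bundle.

    Writes FASTA/GTF, three detector TSVs, DE tables, variant and repeat
    TSVs, miRNA site tables and a ``truth/`` directory; returns the in-memory
    objects for direct pipeline use.
    """
    from circscape import io as cio
    from circscape.burden import classify_exons_for_catalog
    from circscape.introns import extract_flanking_introns, MissingFlankingIntron
    from circscape.motifs import extract_interval_sequence

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    genome, transcripts = generate_genome(config)
    truth_circs = generate_true_circs(config, transcripts)
    calls, call_truth = generate_bsj_calls(config, truth_circs)
    circ_de, lin_de, pairing = generate_de_tables(config, truth_circs)

    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        tx_by_gene.setdefault(tx.gene_name, []).append(tx)
    exon_records = classify_exons_for_catalog(truth_circs, tx_by_gene)
    variants = generate_variants(config, exon_records)

    pairs = []
    tx_by_id = {tx.transcript_id: tx for tx in transcripts}
    for circ in truth_circs:
        try:
            pairs.append(extract_flanking_introns(circ, tx_by_id[circ.transcript_id]))
        except MissingFlankingIntron:
            continue
    alus, alu_truth = generate_alu_annotation(config, pairs)

    intron_seqs = {}
    for pair in pairs:
        intron_seqs[f"{pair.circ_id}|upstream"] = extract_interval_sequence(
            pair.upstream, genome, pair.strand)
        intron_seqs[f"{pair.circ_id}|downstream"] = extract_interval_sequence(
            pair.downstream, genome, pair.strand)
    planted_seqs, motif_truth = plant_motifs(config, intron_seqs)

    circ_seqs = {}
    for circ in truth_circs:
        from circscape.motifs import extract_circ_sequence

        circ_seqs[circ.circ_id] = extract_circ_sequence(
            circ, tx_by_id[circ.transcript_id], genome)
    utr_seqs = {
        tx.gene_name: extract_interval_sequence(tx.exons[-1 if tx.strand == "+" else 0],
                                                genome, tx.strand)
        for tx in transcripts
    }
    circ_seqs, utr_seqs, circ_sites, utr_sites, mirna_truth = generate_mirna_sites(
        config, circ_seqs, utr_seqs)

    # --- write everything as text ---
    cio.write_fasta(genome, outdir / "genome.fa")
    cio.write_gtf(transcripts, outdir / "annotation.gtf")
    sample_cols = [f"sample_{i+1}" for i in range(config.n_samples)]
    for det, det_calls in calls.items():
        rows = [
            {"chrom": c.interval.chrom, "start": c.interval.start,
             "end": c.interval.end, "strand": c.interval.strand,
             **{col: v for col, v in zip(sample_cols, c.counts)}}
            for c in det_calls
        ]
        cio.write_tsv(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"] + sample_cols),
                      outdir / f"bsj_{det}.tsv")
    cio.write_tsv(circ_de, outdir / "de_circ.tsv")
    cio.write_tsv(lin_de, outdir / "de_linear.tsv")
    cio.write_tsv(
        pd.DataFrame(
            [{"chrom": v.chrom, "pos0": v.pos, "pos1": v.pos + 1, "ref": v.ref,
              "alt": v.alt, "impact": v.impact, "flags": ",".join(sorted(v.flags)),
              "cohort": v.cohort} for v in variants]
        ),
        outdir / "variants.tsv",
    )
    cio.write_repeats(alus, outdir / "repeats.tsv")
    cio.write_fasta(planted_seqs, outdir / "flanking_introns.fa")
    cio.write_fasta(circ_seqs, outdir / "circ_sequences.fa")
    cio.write_fasta(utr_seqs, outdir / "utr_sequences.fa")
    site_frame = pd.DataFrame(
        [{"mirna": s.mirna, "target_id": s.target_id, "target_type": s.target_type,
          "position": s.position, "n_sites": s.n_sites, "method": s.method}
         for s in circ_sites + utr_sites]
    )
    cio.write_tsv(site_frame, outdir / "mirna_sites.tsv")
    cio.write_tsv(call_truth, truth_dir / "bsj_calls.tsv")
    cio.write_tsv(pd.DataFrame([{"circ_id": c, "host_gene": g} for c, g in pairing.items()]),
                  truth_dir / "pairing.tsv")
    cio.write_tsv(alu_truth, truth_dir / "alu_planting.tsv")
    cio.write_tsv(motif_truth, truth_dir / "motif_planting.tsv")
    cio.write_tsv(mirna_truth, truth_dir / "mirna_planting.tsv")

    return {
        "genome": genome,
        "transcripts": transcripts,
        "truth_circs": truth_circs,
        "calls": calls,
        "circ_de": circ_de,
        "linear_de": lin_de,
        "pairing": pairing,
        "exon_records": exon_records,
        "variants": variants,
        "pairs": pairs,
        "alus": alus,
        "intron_seqs": planted_seqs,
        "motif_truth": motif_truth,
        "circ_seqs": circ_seqs,
        "utr_seqs": utr_seqs,
        "circ_sites": circ_sites,
        "utr_sites": utr_sites,
        "mirna_truth": mirna_truth,
    }
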