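"""Motif scanning, enrichment against a background set, and positional profiles.

Position-probability-matrix motifs are scored by log-odds against an i.i.d.
background; per-position p-values are exact, computed by dynamic programming
over the discretised score distribution (the FIMO approach). IUPAC consensus
motifs are matched exactly. Enrichment is a one-tailed Fisher test on
hit-bearing sequences, target vs background, with Benjamini-Hochberg
adjustment across motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from circscape.catalog import CircRNA
from circscape.intervals import GenomicInterval, TranscriptModel
from circscape.io import fetch_seq

__all__ = [
    "Motif",
    "MotifHit",
    "EnrichmentResult",
    "PositionalProfile",
    "rna",
    "revcomp_rna",
    "extract_circ_sequence",
    "extract_interval_sequence",
    "scan_sequence",
    "motif_enrichment",
    "positional_profile",
    "read_meme_motifs",
    "read_consensus_motifs",
    "revcomp_motif",
]

RNA_ALPHABET = "ACGU"
_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

_SCALE = 1000  # integer discretisation of bit scores
_PSEUDO = 1e-3


def rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    return rna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """An RNA motif as IUPAC consensus and/or position probability matrix.

    ``ppm`` has shape (length, 4) over A, C, G, U with columns (rows) summing
    to 1.
    """

    name: str
    rbp: str = ""
    consensus: Optional[str] = None
    ppm: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.consensus is None and self.ppm is None:
            raise ValueError(f"motif {self.name}: need consensus or PPM")
        if self.consensus is not None:
            bad = [c for c in rna(self.consensus) if c not in IUPAC]
            if bad:
                raise ValueError(f"motif {self.name}: non-IUPAC symbols {bad}")
            object.__setattr__(self, "consensus", rna(self.consensus))
        if self.ppm is not None:
            ppm = np.asarray(self.ppm, dtype=float)
            if ppm.ndim != 2 or ppm.shape[1] != 4:
                raise ValueError(f"motif {self.name}: PPM must be (L, 4)")
            if not np.allclose(ppm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"motif {self.name}: PPM rows must sum to 1")
            object.__setattr__(self, "ppm", ppm)

    def __len__(self) -> int:
        return len(self.consensus) if self.ppm is None else self.ppm.shape[0]


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    sequence_id: str
    offset: int  # 0-based position in the scanned sequence
    score: float  # log-odds, bits (consensus motifs: length in bases)
    p: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    n_target_with_hit: int
    n_target: int
    n_background_with_hit: int
    n_background: int
    p_fisher: float
    padj_bh: Optional[float] = None


@dataclass(frozen=True)
class PositionalProfile:
    """Binned motif-hit frequency relative to an intron anchor.

    ``frequency[b] = counts[b] / normaliser`` where the normaliser is the
    number of circRNAs in the profiled subset.
    """

    anchor: str  # {"five_prime_end", "bsj_distal_splice_site"}
    bin_width: int
    counts: tuple[int, ...]
    normaliser: int

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.normaliser for c in self.counts)


def extract_circ_sequence(
    circ: CircRNA, transcript: TranscriptModel, genome: Mapping[str, str]
) -> str:
    """RNA sequence of a circRNA: back-spliced exons concatenated in
    transcription order, reverse-complemented for minus-strand transcripts."""
    if circ.bs_exon_indices is None:
        raise ValueError(f"{circ.circ_id} is not annotated to exons")
    i, j = circ.bs_exon_indices
    parts = [
        fetch_seq(genome, e.chrom, e.start, e.end) for e in transcript.exons[i : j + 1]
    ]
    seq = "".join(parts)
    if transcript.strand == "-":
        return revcomp_rna(seq)
    return rna(seq)


def extract_interval_sequence(
    iv: GenomicInterval, genome: Mapping[str, str], strand: Optional[str] = None
) -> str:
    """Strand-aware RNA sequence of a genomic interval (5' -> 3')."""
    seq = fetch_seq(genome, iv.chrom, iv.start, iv.end)
    s = strand if strand is not None else iv.strand
    return revcomp_rna(seq) if s == "-" else rna(seq)


def _int_score_matrix(ppm: np.ndarray, background: np.ndarray) -> np.ndarray:
    adj = (ppm + _PSEUDO) / (1.0 + 4.0 * _PSEUDO)
    bits = np.log2(adj / background)
    return np.rint(bits * _SCALE).astype(np.int64)


def _score_survival(int_matrix: np.ndarray, background: np.ndarray) -> tuple[int, np.ndarray]:
    """Exact distribution of the integer window score under the background.

    Returns ``(min_score, sf)`` where ``sf[s - min_score]`` is
    P(S >= s) for every attainable integer score ``s``.
    """
    lo = int(int_matrix.min(axis=1).sum())
    hi = int(int_matrix.max(axis=1).sum())
    size = hi - lo + 1
    # dist[k] = P(partial score == lo_partial + k)
    dist = np.zeros(1, dtype=float)
    dist[0] = 1.0
    lo_partial = 0
    for row in int_matrix:
        rlo = int(row.min())
        new = np.zeros(dist.size + int(row.max()) - rlo, dtype=float)
        for a in range(4):
            shift = int(row[a]) - rlo
            new[shift : shift + dist.size] += dist * background[a]
        dist = new
        lo_partial += rlo
    assert lo_partial == lo and dist.size == size
    sf = np.cumsum(dist[::-1])[::-1]
    return lo, sf


def _consensus_pvalue(consensus: str, background: np.ndarray) -> float:
    p = 1.0
    for sym in consensus:
        p *= sum(background[_INDEX[b]] for b in IUPAC[sym])
    return p


def _normalise_background(background: Optional[Sequence[float]]) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.all(bg > 0):
        raise ValueError("background must be 4 positive frequencies over ACGU")
    return bg / bg.sum()


def background_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Base composition of a sequence set over A, C, G, U (N ignored)."""
    counts = np.zeros(4, dtype=float)
    for seq in sequences:
        for base in rna(seq):
            idx = _INDEX.get(base)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # floor at a pseudo-frequency so log-odds stay finite
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


def scan_sequence(
    seq: str,
    motif: Motif,
    p_threshold: float = 0.001,
    background: Optional[Sequence[float]] = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Scan one sequence with one motif.

    PPM motifs: every offset is scored by log-odds against the background;
    the per-position p-value is the exact background probability of a score
    at least as high, and offsets with ``p <= p_threshold`` are hits.
    Consensus motifs: IUPAC-compatible exact matches are hits, with p equal
    to the background probability of the consensus. Windows containing N (or
    any non-ACGU symbol) are skipped.
    """
    s = rna(seq)
    bg = _normalise_background(background)
    L = len(motif)
    if L > len(s):
        return []
    encoded = np.array([_INDEX.get(b, -1) for b in s], dtype=np.int64)

    hits: list[MotifHit] = []
    if motif.ppm is not None:
        imat = _int_score_matrix(motif.ppm, bg)
        lo, sf = _score_survival(imat, bg)
        for off in range(len(s) - L + 1):
            window = encoded[off : off + L]
            if np.any(window < 0):
                continue
            iscore = int(imat[np.arange(L), window].sum())
            p = float(sf[iscore - lo])
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        motif_name=motif.name,
                        sequence_id=sequence_id,
                        offset=off,
                        score=iscore / _SCALE,
                        p=p,
                    )
                )
    else:
        consensus = motif.consensus
        allowed = [frozenset(_INDEX[b] for b in IUPAC[sym]) for sym in consensus]
        p_cons = _consensus_pvalue(consensus, bg)
        for off in range(len(s) - L + 1):
            window = encoded[off : off + L]
            if np.any(window < 0):
                continue
            if all(int(b) in ok for b, ok in zip(window, allowed)):
                hits.append(
                    MotifHit(
                        motif_name=motif.name,
                        sequence_id=sequence_id,
                        offset=off,
                        score=float(L),
                        p=p_cons,
                    )
                )
    return hits


def scan_sequences(
    sequences: Mapping[str, str],
    motifs: Sequence[Motif],
    p_threshold: float = 0.001,
    background: Optional[Sequence[float]] = None,
) -> list[MotifHit]:
    """Scan every sequence with every motif."""
    hits: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        for motif in motifs:
            hits.extend(
                scan_sequence(seq, motif, p_threshold=p_threshold,
                              background=background, sequence_id=seq_id)
            )
    return hits


def motif_enrichment(
    targets: Mapping[str, str],
    background_seqs: Mapping[str, str],
    motifs: Sequence[Motif],
    p_threshold: float = 0.001,
    background_freqs: Optional[Sequence[float]] = None,
) -> list[EnrichmentResult]:
    """Per-motif enrichment of hit-bearing sequences in targets vs background.

    One-tailed Fisher exact test on the 2x2 table (sequence has >= 1 hit vs
    none, target vs background); BH adjustment across motifs. Base
    frequencies default to the composition of the background sequence set.
    This presence/absence Fisher test is this package's documented stand-in
    for ranked-enrichment tools; results carry no ranking information.
    """
    if not background_seqs:
        raise ValueError("background sequence set is empty")
    bg = (
        background_frequencies(background_seqs.values())
        if background_freqs is None
        else _normalise_background(background_freqs)
    )
    results = []
    for motif in motifs:
        def has_hit(seq: str) -> bool:
            return bool(scan_sequence(seq, motif, p_threshold=p_threshold, background=bg))

        t_with = sum(1 for s in targets.values() if has_hit(s))
        b_with = sum(1 for s in background_seqs.values() if has_hit(s))
        n_t, n_b = len(targets), len(background_seqs)
        if t_with == 0 and b_with == 0:
            p = 1.0
        else:
            table = [[t_with, n_t - t_with], [b_with, n_b - b_with]]
            p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        results.append(
            EnrichmentResult(
                motif_name=motif.name,
                n_target_with_hit=t_with,
                n_target=n_t,
                n_background_with_hit=b_with,
                n_background=n_b,
                p_fisher=p,
            )
        )
    if results:
        padj = stats.false_discovery_control([r.p_fisher for r in results], method="bh")
        results = [
            EnrichmentResult(**{**r.__dict__, "padj_bh": float(q)})
            for r, q in zip(results, padj)
        ]
    return results


def positional_profile(
    hits: Sequence[MotifHit],
    intron_info: Mapping[str, tuple[int, str]],
    anchor: str = "five_prime_end",
    bin_width: int = 100,
    max_distance: Optional[int] = None,
    normaliser: int = 1,
) -> PositionalProfile:
    """Bin motif hits on flanking introns by distance to an anchor.

    ``intron_info`` maps a hit's ``sequence_id`` to ``(intron_length, side)``
    with side in {"upstream", "downstream"}; hit offsets are positions in the
    extracted intron sequence, 5' -> 3' in transcription orientation.

    ``anchor="five_prime_end"`` measures from the intron's 5' boundary.
    ``anchor="bsj_distal_splice_site"`` measures from the intron boundary
    farther from the BSJ: the 5' end for the upstream intron (whose 3' end
    abuts the back-spliced acceptor exon) and the 3' end for the downstream
    intron. Frequencies are bin counts divided by ``normaliser`` (the number
    of circRNAs in the subset).
    """
    if anchor not in ("five_prime_end", "bsj_distal_splice_site"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if bin_width <= 0 or normaliser <= 0:
        raise ValueError("bin_width and normaliser must be positive")

    distances = []
    for hit in hits:
        try:
            length, side = intron_info[hit.sequence_id]
        except KeyError as exc:
            raise ValueError(f"hit on unknown intron {hit.sequence_id!r}") from exc
        if not (0 <= hit.offset < length):
            raise ValueError(
                f"hit offset {hit.offset} outside intron {hit.sequence_id} (len {length})"
            )
        if anchor == "five_prime_end" or side == "upstream":
            dist = hit.offset
        else:  # downstream intron, distal = 3' end
            dist = length - 1 - hit.offset
        if max_distance is None or dist <= max_distance:
            distances.append(dist)

    if max_distance is not None:
        n_bins = max_distance // bin_width + 1
    else:
        n_bins = (max(distances) // bin_width + 1) if distances else 0
    counts = [0] * n_bins
    for d in distances:
        counts[d // bin_width] += 1
    return PositionalProfile(
        anchor=anchor, bin_width=bin_width, counts=tuple(counts), normaliser=normaliser
    )


def revcomp_motif(motif: Motif) -> Motif:
    """Reverse complement of a motif (for strand-consistency checks)."""
    consensus = None
    if motif.consensus is not None:
        comp = {"A": "U", "C": "G", "G": "C", "U": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        consensus = "".join(comp[c] for c in reversed(motif.consensus))
    ppm = None
    if motif.ppm is not None:
        ppm = motif.ppm[::-1, ::-1].copy()  # reverse positions, A<->U / C<->G
    return Motif(name=f"{motif.name}_rc", rbp=motif.rbp, consensus=consensus,
                 ppm=ppm, source_id=motif.source_id)


def read_meme_motifs(path) -> list[Motif]:
    """Read motifs from MEME minimal format (letter-probability matrices)."""
    import re

    motifs: list[Motif] = []
    name: Optional[str] = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append(Motif(name=name, ppm=np.array(rows)))
                name = stripped.split()[1]
                rows, in_matrix = [], False
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
                rows = []
            elif in_matrix and re.match(r"^[\d.eE+\- \t]+$", stripped) and stripped:
                vals = [float(x) for x in stripped.split()]
                if len(vals) == 4:
                    rows.append(vals)
            elif in_matrix and not stripped:
                in_matrix = False
    if name is not None and rows:
        motifs.append(Motif(name=name, ppm=np.array(rows)))
    return motifs


def read_consensus_motifs(path) -> list[Motif]:
    """Read motifs from a TSV with columns ``name``, ``rbp``, ``consensus``."""
    df = pd.read_csv(path, sep="\t")
    return [
        Motif(name=row["name"], rbp=row.get("rbp", ""), consensus=row["consensus"])
        for _, row in df.iterrows()
    ]
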