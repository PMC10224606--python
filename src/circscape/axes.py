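"""circRNA:miRNA:mRNA axis construction.

Axes join a circRNA and an mRNA that carry binding sites for the same miRNA
and share a differential-expression direction. Site tables are normally
produced by external prediction tools and ingested as TSV; a seed matcher is
provided as an explicitly labelled simplification for testing (its outputs
carry ``method="seed_match"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from circscape.motifs import revcomp_rna, rna

__all__ = [
    "MirnaSite",
    "AxisTriple",
    "seed_match_sites",
    "build_axes",
    "axes_to_frame",
]


@dataclass(frozen=True)
class MirnaSite:
    mirna: str
    target_id: str
    target_type: str  # {"circ", "utr3"}
    position: int  # 0-based offset of the first site
    n_sites: int
    method: str = "external"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.target_type not in ("circ", "utr3"):
            raise ValueError(f"unknown target_type {self.target_type!r}")


@dataclass(frozen=True, order=True)
class AxisTriple:
    circ_id: str
    mirna: str
    mrna_gene: str
    direction: str  # {"up", "down"} shared by circRNA and mRNA


def seed_match_sites(
    seq: str,
    mirna: str,
    mirna_seq: str,
    target_id: str,
    target_type: str,
    seed_span: tuple[int, int] = (2, 8),
    allowed_mismatches: int = 0,
) -> Optional[MirnaSite]:
    """Count seed-complement occurrences of a miRNA in a target sequence.

    The seed is miRNA positions ``seed_span`` (1-based, inclusive; default
    2-8); the target is searched for the reverse complement of the seed,
    allowing up to ``allowed_mismatches`` mismatching bases per window
    (overlapping occurrences counted). Returns ``None`` when no site exists.
    """
    lo, hi = seed_span
    m = rna(mirna_seq)
    if not (1 <= lo <= hi <= len(m)):
        raise ValueError(f"seed span {seed_span} outside miRNA of length {len(m)}")
    site = revcomp_rna(m[lo - 1 : hi])
    target = rna(seq)
    k = len(site)
    positions = [
        off
        for off in range(len(target) - k + 1)
        if sum(a != b for a, b in zip(target[off : off + k], site)) <= allowed_mismatches
    ]
    if not positions:
        return None
    return MirnaSite(
        mirna=mirna, target_id=target_id, target_type=target_type,
        position=positions[0], n_sites=len(positions), method="seed_match",
    )


def build_axes(
    circ_sites: Sequence[MirnaSite],
    utr_sites: Sequence[MirnaSite],
    circ_labels: Mapping[str, str],
    mrna_labels: Mapping[str, str],
) -> tuple[list[AxisTriple], int]:
    """Emit (circRNA, miRNA, mRNA) axes under the same-direction rule.

    A triple is emitted iff the circRNA and the mRNA both carry >= 1 site for
    the same miRNA and both are differentially expressed in the same
    direction (``up`` or ``down``; ``ns`` features never match). Labels come
    from :func:`circscape.concordance.classify_de`. Also returns the maximum
    per-target site count for any single miRNA among the circ site rows.
    """
    circ_by_mirna: dict[str, set[str]] = {}
    for s in circ_sites:
        if s.target_type != "circ":
            raise ValueError(f"circ site table contains target_type {s.target_type!r}")
        circ_by_mirna.setdefault(s.mirna, set()).add(s.target_id)
    utr_by_mirna: dict[str, set[str]] = {}
    for s in utr_sites:
        if s.target_type != "utr3":
            raise ValueError(f"3'UTR site table contains target_type {s.target_type!r}")
        utr_by_mirna.setdefault(s.mirna, set()).add(s.target_id)

    axes: set[AxisTriple] = set()
    for mirna, circs in circ_by_mirna.items():
        mrnas = utr_by_mirna.get(mirna, set())
        for circ_id in circs:
            direction = circ_labels.get(circ_id, "ns")
            if direction == "ns":
                continue
            for mrna in mrnas:
                if mrna_labels.get(mrna, "ns") == direction:
                    axes.add(AxisTriple(circ_id=circ_id, mirna=mirna,
                                        mrna_gene=mrna, direction=direction))
    max_sites = max((s.n_sites for s in circ_sites), default=0)
    return sorted(axes), max_sites


def axes_to_frame(axes: Sequence[AxisTriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"circ_id": a.circ_id, "mirna": a.mirna,
             "mrna_gene": a.mrna_gene, "direction": a.direction}
            for a in axes
        ],
        columns=["circ_id", "mirna", "mrna_gene", "direction"],
    )
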