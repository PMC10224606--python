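"""Post-model statistics on differential-expression and exon-usage tables.

Operates on tables produced upstream by count-model fitting (which is out of
scope here): circ/linear log2-fold-change concordance, exon-bin aggregation,
differential-splicing classification, hypergeometric over-representation
tests and the shared two-sample Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "OraResult",
    "ZTestResult",
    "classify_de",
    "lfc_correlation",
    "fold_ratio_stats",
    "aggregate_exon_bins",
    "classify_spliced_genes",
    "splicing_rate_test",
    "gene_set_ora",
    "two_sample_z_test",
    "wilcoxon_rank_sum",
    "dedup_lfc_min_max",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class OraResult:
    """Hypergeometric over-representation of a gene set.

    ``p`` is the upper-tail probability P(X >= k) for drawing ``n`` genes from
    a universe of ``N`` containing ``K`` set members and observing ``k`` in
    the overlap.
    """

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    rate_ratio: float
    padj: Optional[float] = None


@dataclass(frozen=True)
class ZTestResult:
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    z: float
    p: float


def classify_de(
    records: pd.DataFrame, lfc_threshold: float = 2.0, padj_threshold: float = 0.05
) -> pd.Series:
    """Label each record ``up``/``down``/``ns``.

    ``up`` iff ``lfc >= +lfc_threshold`` (inclusive) and ``padj <
    padj_threshold``; ``down`` symmetric; missing padj is ``ns``. Expects
    columns ``lfc`` and ``padj``.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = records["lfc"]
    padj = records["padj"]
    sig = padj.notna() & (padj < padj_threshold)
    labels = pd.Series("ns", index=records.index, dtype=object)
    labels[sig & (lfc >= lfc_threshold)] = "up"
    labels[sig & (lfc <= -lfc_threshold)] = "down"
    return labels


def lfc_correlation(
    circ: pd.DataFrame,
    linear: pd.DataFrame,
    pairing: Mapping[str, str],
) -> tuple[float, float, int]:
    """Pearson correlation of circRNA vs linear-host log2 fold changes.

    ``pairing`` maps circ ``feature_id`` to host ``feature_id``; records
    without a partner are dropped. Returns ``(R, p, n_pairs)``.
    """
    circ_lfc = circ.set_index("feature_id")["lfc"]
    lin_lfc = linear.set_index("feature_id")["lfc"]
    xs, ys = [], []
    for cid, hid in pairing.items():
        if cid in circ_lfc.index and hid in lin_lfc.index:
            x, y = circ_lfc[cid], lin_lfc[hid]
            if pd.notna(x) and pd.notna(y):
                xs.append(float(x))
                ys.append(float(y))
    if len(xs) < 3:
        raise InsufficientDataError(f"only {len(xs)} matched pairs; need >= 3")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), len(xs)


def fold_ratio_stats(
    pairs: Sequence[tuple[float, float]],
    margin_log2: float = 1.0,
    top_n: Optional[int] = None,
) -> tuple[float, float]:
    """Circ-over-linear fold-change excess statistics.

    ``pairs`` are ``(lfc_circ, lfc_linear)``. Returns the fraction of pairs
    whose excess ``lfc_circ - lfc_linear`` strictly exceeds ``margin_log2``
    (two-fold for the default margin of 1), and the mean linear-scale fold
    excess ``2**(lfc_circ - lfc_linear)`` over the ``top_n`` pairs ranked by
    circ LFC (all pairs when ``top_n`` is None).
    """
    if not pairs:
        raise InsufficientDataError("no pairs supplied")
    excess = np.array([c - l for c, l in pairs], dtype=float)
    frac = float(np.mean(excess > margin_log2))
    order = np.argsort([-c for c, _ in pairs], kind="stable")
    top = order if top_n is None else order[:top_n]
    mean_fold = float(np.mean(2.0 ** excess[top]))
    return frac, mean_fold


def aggregate_exon_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Aggregate exon bins to annotated exons.

    Per exon: LFC = arithmetic mean of bin LFC estimates, padj = minimum bin
    padj (so an exon qualifies whenever any bin does), base_mean = mean.
    Expects columns ``gene_id``, ``exon_id``, ``lfc_estimate``, ``padj``,
    ``base_mean``.
    """
    agg = (
        bins.groupby(["gene_id", "exon_id"], sort=True)
        .agg(
            lfc=("lfc_estimate", "mean"),
            padj=("padj", "min"),
            base_mean=("base_mean", "mean"),
            n_bins=("exon_id", "size"),
        )
        .reset_index()
    )
    return agg


def classify_spliced_genes(
    bins: pd.DataFrame,
    lfc_threshold: float = 2.0,
    padj_threshold: float = 0.05,
    base_mean_threshold: float = 10.0,
) -> tuple[pd.Series, set[str]]:
    """Differentially used exon bins and differentially spliced genes.

    A bin is differentially used when |LFC| >= ``lfc_threshold``, padj <
    ``padj_threshold`` and base mean > ``base_mean_threshold``; a gene is
    differentially spliced when at least one of its bins qualifies.
    """
    used = (
        (bins["lfc_estimate"].abs() >= lfc_threshold)
        & bins["padj"].notna()
        & (bins["padj"] < padj_threshold)
        & (bins["base_mean"] > base_mean_threshold)
    )
    spliced_genes = set(bins.loc[used, "gene_id"].unique())
    return used, spliced_genes


def _hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def splicing_rate_test(universe: set, spliced: set, subset: set, set_name: str = "subset") -> OraResult:
    """Is a gene subset enriched for differentially spliced genes?

    Upper-tail hypergeometric probability P(X >= k) with N = |universe|,
    K = |spliced|, n = |subset| and k = |subset & spliced|, plus the splicing
    rate ratio (k/n)/(K/N).
    """
    if not subset:
        raise InsufficientDataError("subset is empty")
    if not subset <= universe or not spliced <= universe:
        raise ValueError("subset and spliced must be contained in the universe")
    N, K, n = len(universe), len(spliced), len(subset)
    k = len(subset & spliced)
    ratio = (k / n) / (K / N) if K else math.nan
    return OraResult(set_name=set_name, k=k, K=K, n=n, N=N,
                     p=_hypergeom_upper(k, N, K, n), rate_ratio=ratio)


def gene_set_ora(
    universe: set,
    selected: set,
    gene_sets: Mapping[str, set],
) -> list[OraResult]:
    """Over-representation of each gene set among selected genes, with
    Benjamini-Hochberg adjustment across sets.

    Gene sets are intersected with the universe first; a set disjoint from
    the universe yields p = 1.
    """
    if not selected <= universe:
        raise ValueError("selected must be contained in the universe")
    results = []
    for name, gene_set in gene_sets.items():
        gs = gene_set & universe
        if not gs:
            import warnings

            warnings.warn(f"gene set {name!r} is disjoint from the universe")
        N, K, n = len(universe), len(gs), len(selected)
        k = len(selected & gs)
        p = _hypergeom_upper(k, N, K, n) if K else 1.0
        ratio = (k / n) / (K / N) if K and n else math.nan
        results.append(OraResult(set_name=name, k=k, K=K, n=n, N=N, p=p, rate_ratio=ratio))
    if results:
        padj = stats.false_discovery_control([r.p for r in results], method="bh")
        results = [
            OraResult(**{**r.__dict__, "padj": float(q)}) for r, q in zip(results, padj)
        ]
    return results


def two_sample_z_test(values_a: Sequence[float], values_b: Sequence[float]) -> ZTestResult:
    """Two-sample Z-test on group means with unbiased (n-1) standard errors.

    z = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    Zero variance in both groups with equal means gives z = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("both groups need at least 2 values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    se_a = float(a.std(ddof=1) / math.sqrt(a.size))
    se_b = float(b.std(ddof=1) / math.sqrt(b.size))
    denom = math.hypot(se_a, se_b)
    if denom == 0.0:
        z = 0.0 if mean_a == mean_b else math.copysign(math.inf, mean_a - mean_b)
    else:
        z = (mean_a - mean_b) / denom
    p = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return ZTestResult(mean_a=mean_a, mean_b=mean_b, se_a=se_a, se_b=se_b, z=z, p=p)


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact for small tie-free samples (n < 25 per group), otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    small = a.size < 25 and b.size < 25
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dedup_lfc_min_max(records: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Collapse duplicate host-gene entries to one LFC per gene.

    Table-preparation helper for rank-based enrichment tools that require a
    single entry per gene: among positively regulated records the maximum LFC
    is kept per host gene, among negatively regulated records the minimum.
    Expects columns ``gene`` and ``lfc``; ``direction`` is ``"up"`` or
    ``"down"``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    agg = "max" if direction == "up" else "min"
    return records.groupby("gene", as_index=False).agg(lfc=("lfc", agg))
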