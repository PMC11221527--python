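"""Depth normalization and one-cluster-vs-rest Wilcoxon marker testing.

Normalization here is a deliberately simple, documented stand-in for
regularized-NB approaches: per-spot totals are scaled to the median spot
total and counts are log2(1 + scaled).  The spatial statistics downstream
are contract-agnostic to the normalization choice; the substitution is
recorded in the output metadata of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NORMALIZATION_NAME = "log1p_median_scaled"  # log base 2, pseudocount 1
NORMALIZATION_NOTE = (
    "counts scaled so each spot's total equals the median spot total, then "
    "log2(1 + scaled); simple depth normalization used in place of a "
    "regularized negative-binomial model"
)


@dataclass
class NormalizedMatrix:
    """Genes x spots normalized expression with per-spot scale factors."""

    matrix: np.ndarray
    scale_factors: np.ndarray
    normalization: str = NORMALIZATION_NAME
    excluded_spots: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]


def normalize(counts: np.ndarray) -> NormalizedMatrix:
    """Median-depth scaling followed by log2(1 + x).

    Spots with zero total counts carry no information and are excluded
    (their columns dropped) with a warning; ``excluded_spots`` records
    their positional indices in the input.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D genes x spots matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        warnings.warn(
            f"excluding {len(zero)} spot(s) with zero total counts", stacklevel=2
        )
        counts = np.delete(counts, zero, axis=1)
        totals = np.delete(totals, zero)
    if counts.shape[1] == 0:
        raise ValueError("no spots with nonzero totals")
    scale = np.median(totals) / totals
    return NormalizedMatrix(
        matrix=np.log2(1.0 + counts * scale[None, :]),
        scale_factors=scale,
        excluded_spots=zero,
    )


def expression_fraction_filter(
    counts: np.ndarray, gene_ids, threshold: float = 0.10
) -> list:
    """Genes detected (nonzero) in strictly more than ``threshold`` of spots.

    Implements the "greater than 10% expression" gate as the fraction of
    spots with nonzero counts; the boundary is exclusive, so a gene seen
    in exactly 10% of spots is dropped.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    counts = np.asarray(counts)
    frac = (counts > 0).mean(axis=1)
    gene_ids = list(gene_ids)
    return [g for g, f in zip(gene_ids, frac) if f > threshold]


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have <= 50 observations and
    the pooled values are tie-free; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 50 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(p, method="bh")


def cluster_markers(
    matrix: np.ndarray,
    gene_ids,
    clusters: np.ndarray,
    target: int,
    min_logfc: float = 0.1,
    alpha: float = 0.05,
    rest: str = "assigned",
    all_results: bool = False,
) -> pd.DataFrame:
    """One-cluster-vs-rest differential expression on normalized values.

    For each gene the spots of ``target`` are compared against the rest
    with a two-sided Wilcoxon rank-sum test; the log2 fold change is
    computed from pseudocounted group means,
    ``log2(mean_target + 1) - log2(mean_rest + 1)``.  Reported markers
    satisfy ``|log_fc| > min_logfc`` and unadjusted ``p < alpha``
    (BH-adjusted p-values are included for reference but not used to
    filter), sorted by p.

    Parameters
    ----------
    rest
        ``"assigned"`` (default): the comparison group is the spots
        assigned to any other hotspot cluster, mirroring a
        one-vs-remaining-clusters design.  ``"all"``: every non-target
        spot, including unassigned ones.
    """
    matrix = np.asarray(matrix, dtype=float)
    clusters = np.asarray(clusters)
    gene_ids = list(gene_ids)
    if matrix.shape[1] != len(clusters):
        raise ValueError("cluster labels must align with matrix columns")
    if target not in set(clusters.tolist()):
        raise ValueError(f"target cluster {target} absent from labels")
    if rest not in ("assigned", "all"):
        raise ValueError("rest must be 'assigned' or 'all'")
    t_mask = clusters == target
    if rest == "assigned":
        r_mask = (clusters != target) & (clusters != 0)
    else:
        r_mask = ~t_mask
    if t_mask.sum() < 3 or r_mask.sum() < 3:
        raise ValueError(
            f"need >= 3 spots per side, got target={int(t_mask.sum())}, "
            f"rest={int(r_mask.sum())}"
        )

    tgt, rst = matrix[:, t_mask], matrix[:, r_mask]
    log_fc = np.log2(tgt.mean(axis=1) + 1.0) - np.log2(rst.mean(axis=1) + 1.0)
    pvals = np.array([wilcoxon_rank_sum(tgt[g], rst[g]) for g in range(len(gene_ids))])
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "target_cluster": target,
            "log_fc": log_fc,
            "p": pvals,
            "p_adj": _bh_adjust(pvals),
            "pct_target": (tgt > 0).mean(axis=1),
            "pct_rest": (rst > 0).mean(axis=1),
        }
    )
    if not all_results:
        out = out[(out["log_fc"].abs() > min_logfc) & (out["p"] < alpha)]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
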