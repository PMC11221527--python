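"""Neighborhood-covariate correlation screen and heatmap preprocessing.

Per-sample mean expression is screened against zip-code-level
neighborhood measures (violent crime rate per 1,000 residents, overall
crime rate, % poverty, racial/ethnic composition) with Pearson
correlation; significance uses the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
Housekeeping genes are removed before visualization, and heatmap rows
are ordered by average-linkage hierarchical clustering of log-transformed
values while columns follow ascending violent-crime rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

COVARIATE_COLUMNS = [
    "violent_crime_rate",
    "overall_crime_rate",
    "pct_poverty",
    "pct_black",
    "pct_white",
    "pct_hispanic",
]

# Small canonical housekeeping symbol set; user-overridable.
DEFAULT_HOUSEKEEPING = (
    "ACTB", "GAPDH", "B2M", "TUBB", "RPL13A", "HPRT1", "TBP", "GUSB",
    "PPIA", "PGK1", "RPLP0", "SDHA", "YWHAZ", "UBC", "HMBS", "TFRC",
    "POLR2A", "RPS18", "EEF1A1", "ALAS1",
)


@dataclass
class HeatmapOrder:
    """Row/column ordering metadata for a correlation heatmap."""

    row_order: np.ndarray
    col_order: np.ndarray
    transformed: pd.DataFrame
    linkage_matrix: np.ndarray | None
    transform: str = "log2(x + 1)"


def sample_means(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample mean expression over the shared gene universe.

    ``matrices`` maps sample id to a genes x spots DataFrame of
    normalized values (in-tissue spots).  Genes are intersected across
    samples; dropped genes are reported with a warning.  Means are
    arithmetic over spots.
    """
    if not matrices:
        raise ValueError("no samples provided")
    gene_sets = [set(df.index) for df in matrices.values()]
    shared = sorted(set.intersection(*gene_sets))
    if not shared:
        raise ValueError("no genes shared across all samples")
    dropped = len(set.union(*gene_sets)) - len(shared)
    if dropped:
        warnings.warn(
            f"dropping {dropped} gene(s) absent from at least one sample",
            stacklevel=2,
        )
    return pd.DataFrame(
        {sid: df.loc[shared].mean(axis=1) for sid, df in matrices.items()},
        index=shared,
    )


def correlate_genes(
    means: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate: str = "violent_crime_rate",
    alpha: float = 0.05,
    all_results: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each gene's per-sample mean with a covariate.

    Returns genes with two-sided ``p < alpha`` (or everything when
    ``all_results``), with the sign of r reported as a direction
    (up/down).  Constant genes are skipped with a warning; a constant
    covariate is an error (correlation undefined).
    """
    if covariate not in covariates.columns:
        raise ValueError(f"covariate {covariate!r} not in table")
    samples = [s for s in means.columns if s in covariates.index]
    x = covariates.loc[samples, covariate].to_numpy(dtype=float)
    finite = np.isfinite(x)
    samples = [s for s, f in zip(samples, finite) if f]
    x = x[finite]
    n = len(samples)
    if n < 3:
        raise ValueError(f"need >= 3 samples with finite covariate values, got {n}")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant; correlation undefined")

    m = means[samples].to_numpy(dtype=float)
    mc = m - m.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    sg = np.sqrt((mc**2).sum(axis=1))
    constant = sg == 0
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} constant gene(s)", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ xc) / (sg * sx)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly

    out = pd.DataFrame(
        {
            "gene_id": means.index,
            "covariate": covariate,
            "r": r,
            "p": p,
            "n": n,
            "direction": np.where(r >= 0, "up", "down"),
        }
    )[~constant]
    if not all_results:
        out = out[out["p"] < alpha]
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def remove_housekeeping(genes, hk_list=None) -> list:
    """Case-insensitive removal of housekeeping symbols from a gene list."""
    hk = {g.upper() for g in (DEFAULT_HOUSEKEEPING if hk_list is None else hk_list)}
    kept = [g for g in genes if str(g).upper() not in hk]
    if genes and not kept:
        warnings.warn("all genes were housekeeping genes; result is empty",
                      stacklevel=2)
    return kept


def heatmap_order(
    matrix: pd.DataFrame,
    crime_rates: pd.Series,
    method: str = "average",
    metric: str = "euclidean",
    pseudocount: float = 1.0,
) -> HeatmapOrder:
    """Ordering metadata for the correlation heatmap.

    Rows (genes) are ordered by agglomerative hierarchical clustering
    (average linkage, Euclidean distance by default) of
    ``log2(x + pseudocount)``; columns (samples) are ordered by
    ascending violent-crime rate, not clustered.
    """
    log_m = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    if not np.isfinite(log_m).all():
        raise ValueError("matrix is not finite after the log transform")
    rates = crime_rates.loc[matrix.columns].to_numpy(dtype=float)
    col_order = np.argsort(rates, kind="stable")
    if matrix.shape[0] < 2:
        row_order, link = np.arange(matrix.shape[0]), None
    else:
        link = hierarchy.linkage(log_m, method=method, metric=metric)
        row_order = np.asarray(hierarchy.leaves_list(link))
    transformed = pd.DataFrame(log_m, index=matrix.index, columns=matrix.columns)
    transformed = transformed.iloc[row_order, col_order]
    return HeatmapOrder(
        row_order=row_order,
        col_order=col_order,
        transformed=transformed,
        linkage_matrix=link,
    )
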