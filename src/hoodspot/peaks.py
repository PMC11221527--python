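"""Paired peak-set operations for tumor/normal cistrome comparison.

Peak sets are genomic intervals (0-based half-open, BED convention)
carrying a fold-enrichment score — BED6 score column or narrowPeak
signalValue.  Supported operations mirror a tumor/normal binding-site
workflow: whole-record interval subtraction ("filter out regions also
found in ..."), top-enrichment-fraction selection, two-sample
Kolmogorov–Smirnov comparison of enrichment scores, strand-aware
TSS-relative binning, and k-means clustering of site x condition signal
matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PEAK_COLUMNS = ["chrom", "start", "end", "name", "enrichment", "strand"]

DEFAULT_TSS_BINS = (
    "promoter_le1kb",
    "upstream_1to3kb",
    "upstream_3to10kb",
    "genebody_downstream_1to10kb",
    "distal_gt10kb",
)


class PeakFormatError(ValueError):
    """Malformed peak record or file."""


@dataclass
class PeakSet:
    """Genomic intervals with enrichment scores, sorted by (chrom, start)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("chrom", "start", "end", "enrichment") if c not in df]
        if missing:
            raise PeakFormatError(f"peak table missing columns: {missing}")
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise PeakFormatError(
                f"interval with start >= end at record {bad[0]}: "
                f"{df.loc[bad[0], ['chrom', 'start', 'end']].tolist()}"
            )
        if not np.isfinite(df["enrichment"].to_numpy(dtype=float)).all():
            raise PeakFormatError("non-finite enrichment score")
        self.records = (
            df.sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def enrichment(self) -> np.ndarray:
        return self.records["enrichment"].to_numpy(dtype=float)

    def midpoints(self) -> np.ndarray:
        return (
            self.records["start"].to_numpy() + self.records["end"].to_numpy()
        ) // 2


@dataclass
class PeakComparison:
    """Two-sample KS comparison of enrichment score distributions."""

    ks_d: float
    p: float
    n_a: int
    n_b: int
    direction: int  # sign of median(a) - median(b)


@dataclass
class SignalClusters:
    """k-means clustering of a site x condition enrichment matrix."""

    assignment: np.ndarray
    centers: np.ndarray
    inertia: float
    k: int
    seed: int | None


def read_bed(path, enrichment_col: int = 4) -> PeakSet:
    """Read a BED6 (or BED3+) peak file; the score column is the enrichment."""
    return _read_peak_table(path, enrichment_col=enrichment_col, summit_col=None)


def read_narrowpeak(path) -> PeakSet:
    """Read an ENCODE narrowPeak file (BED6+4; column 7 = signalValue,
    column 10 = summit offset, -1 when absent)."""
    return _read_peak_table(path, enrichment_col=6, summit_col=9)


def _read_peak_table(path, enrichment_col, summit_col) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise PeakFormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise PeakFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise PeakFormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            enr = float(f[enrichment_col]) if len(f) > enrichment_col else 0.0
            rows.append(
                {
                    "chrom": f[0],
                    "start": start,
                    "end": end,
                    "name": f[3] if len(f) > 3 else f"peak{lineno}",
                    "enrichment": enr,
                    "strand": f[5] if len(f) > 5 else ".",
                    "summit": int(f[summit_col])
                    if summit_col is not None and len(f) > summit_col
                    else -1,
                }
            )
    if not rows:
        raise PeakFormatError(f"{path}: no peak records")
    return PeakSet(pd.DataFrame(rows))


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6 with the enrichment score in column 5."""
    df = peaks.records
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            strand = getattr(rec, "strand", ".")
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t"
                f"{rec.enrichment:g}\t{strand}\n"
            )


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS TSV with columns chrom, tss_position, strand, gene_id."""
    tss = pd.read_csv(path, sep="\t")
    required = {"chrom", "tss_position", "strand", "gene_id"}
    if not required.issubset(tss.columns):
        raise PeakFormatError(f"TSS table must have columns {sorted(required)}")
    return tss


def _overlap_lengths(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Total overlapping base pairs of each record of a with the merged b."""
    out = np.zeros(len(a), dtype=np.int64)
    a_df = a.records
    for chrom, b_chr in b.records.groupby("chrom", sort=False):
        a_idx = np.flatnonzero((a_df["chrom"] == chrom).to_numpy())
        if len(a_idx) == 0:
            continue
        # merge b intervals on this chromosome
        starts, ends = [], []
        for s, e in zip(b_chr["start"], b_chr["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        ms, me = np.asarray(starts), np.asarray(ends)
        cum = np.concatenate([[0], np.cumsum(me - ms)])

        def covered(pos):  # total merged-b coverage in [0, pos)
            j = np.searchsorted(ms, pos, side="left")
            inside = np.clip(pos - ms[np.maximum(j - 1, 0)], 0, (me - ms)[np.maximum(j - 1, 0)])
            inside[j == 0] = 0
            return cum[np.maximum(j - 1, 0)] + inside

        a_s = a_df["start"].to_numpy()[a_idx]
        a_e = a_df["end"].to_numpy()[a_idx]
        out[a_idx] = covered(a_e) - covered(a_s)
    return out


def subtract_intervals(
    a: PeakSet, b: PeakSet, min_overlap_frac: float | None = None
) -> PeakSet:
    """Records of ``a`` that do not overlap any record of ``b``.

    Whole-record semantics: a record of ``a`` sharing at least one base
    pair with ``b`` is removed entirely (never truncated), mirroring
    bed-style blacklisting.  ``min_overlap_frac`` raises the removal
    threshold to that fraction of the a-record's length.
    """
    if len(a) == 0 or len(b) == 0:
        return PeakSet(a.records.copy())
    ov = _overlap_lengths(a, b)
    if min_overlap_frac is None:
        keep = ov == 0
    else:
        if not (0.0 < min_overlap_frac <= 1.0):
            raise ValueError("min_overlap_frac must lie in (0, 1]")
        lengths = (a.records["end"] - a.records["start"]).to_numpy()
        keep = ov < min_overlap_frac * lengths
    return PeakSet(a.records[keep].reset_index(drop=True))


def top_fraction(peaks: PeakSet, frac: float = 0.10) -> PeakSet:
    """The ``ceil(frac * n)`` records with highest enrichment.

    Ties at the boundary break deterministically by (chrom, start)
    order.  The 10% default mirrors a high-confidence top-decile cutoff.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must lie in (0, 1], got {frac}")
    n = len(peaks)
    if n == 0:
        warnings.warn("top_fraction of an empty peak set", stacklevel=2)
        return PeakSet(peaks.records.copy())
    m = math.ceil(frac * n)
    df = peaks.records
    order = df.sort_values(
        ["enrichment", "chrom", "start"],
        ascending=[False, True, True],
        kind="stable",
    )
    return PeakSet(order.head(m).reset_index(drop=True))


def compare_enrichment(a: PeakSet, b: PeakSet) -> PeakComparison:
    """Two-sided two-sample KS test on enrichment scores.

    Uses the exact null distribution when ``n_a * n_b <= 10,000`` and
    the asymptotic distribution otherwise.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both peak sets must be non-empty")
    sa, sb = a.enrichment, b.enrichment
    method = "exact" if len(sa) * len(sb) <= 10_000 else "asymp"
    res = stats.ks_2samp(sa, sb, alternative="two-sided", method=method)
    return PeakComparison(
        ks_d=float(res.statistic),
        p=float(res.pvalue),
        n_a=len(sa),
        n_b=len(sb),
        direction=int(np.sign(np.median(sa) - np.median(sb))),
    )


def tss_distances(peaks: PeakSet, tss: pd.DataFrame) -> np.ndarray:
    """Signed strand-aware distance of each peak anchor to the nearest TSS.

    The anchor is the summit position when a non-negative summit offset
    is present, otherwise the interval midpoint.  Positive distances are
    downstream of the TSS in gene orientation (for a − strand gene,
    genomic positions below the TSS are downstream).
    """
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    anchors = peaks.midpoints().astype(np.int64)
    if "summit" in peaks.records:
        summit = peaks.records["summit"].to_numpy()
        has = summit >= 0
        anchors[has] = (peaks.records["start"].to_numpy()[has] + summit[has])
    dist = np.zeros(len(peaks), dtype=np.int64)
    for chrom, grp in peaks.records.groupby("chrom", sort=False):
        sub = tss[tss["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"peak chromosome {chrom!r} absent from TSS table")
        order = np.argsort(sub["tss_position"].to_numpy())
        pos = sub["tss_position"].to_numpy()[order]
        strand = sub["strand"].to_numpy()[order]
        mids = anchors[grp.index.to_numpy()]
        j = np.searchsorted(pos, mids)
        left = np.clip(j - 1, 0, len(pos) - 1)
        right = np.clip(j, 0, len(pos) - 1)
        pick = np.where(
            np.abs(mids - pos[left]) <= np.abs(pos[right] - mids), left, right
        )
        signed = mids - pos[pick]
        signed[strand[pick] == "-"] *= -1
        dist[grp.index.to_numpy()] = signed
    return dist


def annotate_distribution(
    peaks: PeakSet, tss: pd.DataFrame
) -> tuple[dict[str, float], np.ndarray]:
    """TSS-relative category fractions for a peak set.

    Bins (on the signed strand-aware distance d, positive downstream):
    promoter |d| <= 1 kb; upstream 1–3 kb and 3–10 kb (d < 0); gene
    body / downstream 1–10 kb (d > 0); distal intergenic |d| > 10 kb.
    Fractions over peaks sum to 1.
    """
    d = tss_distances(peaks, tss)
    cats = np.empty(len(d), dtype=object)
    cats[np.abs(d) <= 1000] = "promoter_le1kb"
    cats[(d < -1000) & (d >= -3000)] = "upstream_1to3kb"
    cats[(d < -3000) & (d >= -10000)] = "upstream_3to10kb"
    cats[(d > 1000) & (d <= 10000)] = "genebody_downstream_1to10kb"
    cats[np.abs(d) > 10000] = "distal_gt10kb"
    fractions = {
        b: float((cats == b).sum() / len(cats)) for b in DEFAULT_TSS_BINS
    }
    return fractions, cats


def signal_kmeans(
    matrix: np.ndarray,
    k: int = 7,
    seed: int | None = None,
    n_init: int = 10,
) -> SignalClusters:
    """k-means clustering of a site x condition enrichment matrix.

    Lloyd's algorithm with k-means++ initialization and ``n_init``
    restarts (best inertia kept); deterministic given ``seed``.  The
    default k of 7 mirrors a seven-cluster binding-signal panel.
    """
    from sklearn.cluster import KMeans

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (sites x conditions)")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix must be finite")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of sites ({matrix.shape[0]})")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, random_state=seed,
        algorithm="lloyd",
    ).fit(matrix)
    return SignalClusters(
        assignment=km.labels_.astype(int),
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        k=k,
        seed=seed,
    )
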