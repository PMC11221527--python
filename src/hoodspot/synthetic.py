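"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the three analysis arms:

* :func:`simulate_expression` — negative-binomial spot counts on a hex
  lattice with spatially contiguous planted high-expression discs
  (hotspots), for the local Moran / hotspot-DE arm.
* :func:`simulate_study` — a multi-sample design in which a subset of
  genes' per-sample mean expression is linear in the neighborhood
  violent-crime rate plus Gaussian noise, for the correlation screen.
* :func:`simulate_peaks` — paired tumor/normal peak sets sharing a
  controlled fraction of coordinates, with tumor enrichment scores
  shifted by a planted location shift, for the cistrome comparison.

Every generator is a pure function of its spec including the seed;
substreams for independent components are derived from one root
``SeedSequence`` so components stay independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import SpotGrid, hex_distance, make_hex_grid

__all__ = [
    "HotspotSpec",
    "StudyDesign",
    "PeakSimSpec",
    "make_hex_grid",
    "default_covariate_table",
    "simulate_expression",
    "simulate_study",
    "simulate_peaks",
]


@dataclass
class HotspotSpec:
    """A planted contiguous high-expression region.

    ``center`` is a lattice coordinate (row, col); ``radius`` a hex
    lattice distance; ``fold_elevation`` the multiplicative mean
    increase applied to ``affected_genes`` inside the disc.
    """

    center: tuple[int, int]
    radius: int
    fold_elevation: float
    affected_genes: list[str]
    allow_flat: bool = False  # permit fold_elevation == 1 (no-signal spec)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.fold_elevation < 1.0 or (
            self.fold_elevation == 1.0 and not self.allow_flat
        ):
            raise ValueError(
                "fold_elevation must exceed 1 (set allow_flat=True for a "
                "deliberate no-signal spec with fold_elevation == 1)"
            )
        if not self.affected_genes:
            raise ValueError("affected_genes must be non-empty")


@dataclass
class StudyDesign:
    """A multi-sample study with covariate-linked genes.

    Defaults mirror a 15-patient design with five samples in each of
    three violence-exposure tiers.  For covariate-linked genes the
    per-sample mean expression is
    ``baseline + effect_slope * violent_crime_rate + N(0, noise_sd)``;
    all other genes have slope 0.
    """

    n_samples: int = 15
    n_genes: int = 1000
    n_covariate_genes: int = 50
    effect_slope: float = 0.05
    noise_sd: float = 0.5
    baseline: float = 5.0
    covariates: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_covariate_genes > self.n_genes:
            raise ValueError("n_covariate_genes must be <= n_genes")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.covariates is not None:
            tab = self.covariates
            num = [c for c in tab.columns if c.startswith(("pct_", "violent", "overall"))]
            if (tab[num] < 0).any().any():
                raise ValueError("covariate values must be >= 0")
            pct = [c for c in tab.columns if c.startswith("pct_")]
            if (tab[pct] > 100).any().any():
                raise ValueError("percentages must lie in [0, 100]")


@dataclass
class PeakSimSpec:
    """Paired tumor/normal peak simulation parameters.

    ``shared_fraction`` of the smaller side's peaks appear at identical
    coordinates in both sets; the remaining peaks are disjoint between
    sets.  Tumor enrichment scores receive an additive
    ``enrichment_shift`` on top of the common N(4, 1) score model.
    """

    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_peaks_tumor: int = 200
    n_peaks_normal: int = 200
    shared_fraction: float = 0.3
    enrichment_shift: float = 0.0
    peak_width: int = 300
    score_mean: float = 4.0
    score_sd: float = 1.0
    n_tss_per_chrom: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.chrom_length <= self.peak_width:
            raise ValueError("chrom_length must exceed peak_width")
        if self.n_peaks_tumor < 1 or self.n_peaks_normal < 1:
            raise ValueError("peak counts must be >= 1")


def simulate_expression(
    grid: SpotGrid,
    n_genes: int,
    nb_mean: float = 5.0,
    nb_dispersion: float = 10.0,
    hotspots: list[HotspotSpec] | None = None,
    seed: int | None = None,
):
    """Negative-binomial spot counts with planted hotspot discs.

    Counts are NB with mean ``nb_mean`` (variance mu + mu^2/dispersion);
    inside each hotspot disc the mean of the hotspot's affected genes is
    multiplied by ``fold_elevation`` (a :class:`HotspotSpec` built with
    ``allow_flat=True`` may plant a degenerate no-signal disc for
    null-calibration studies).

    Returns
    -------
    (counts, gene_ids, truth)
        ``counts``: genes x spots int matrix; ``truth``: DataFrame of
        per-spot membership flags, one boolean column per hotspot.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if nb_mean <= 0 or nb_dispersion <= 0:
        raise ValueError("nb_mean and nb_dispersion must be positive")
    hotspots = list(hotspots or [])
    gene_ids = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    known = set(gene_ids)
    n_spots = grid.n_spots
    mu = np.full((n_genes, n_spots), float(nb_mean))
    truth = pd.DataFrame({"barcode": grid.barcodes.to_numpy()})
    for h_idx, h in enumerate(hotspots):
        if not grid.contains(*h.center):
            raise ValueError(f"hotspot center {h.center} is not a grid spot")
        unknown = [g for g in h.affected_genes if g not in known]
        if unknown:
            raise ValueError(f"affected genes not in the simulated panel: {unknown}")
        inside = grid.hex_distance_from(h.center) <= h.radius
        rows = [gene_ids.index(g) for g in h.affected_genes]
        mu[np.ix_(rows, inside)] *= h.fold_elevation
        truth[f"hotspot_{h_idx}"] = inside
    rng = np.random.default_rng(seed)
    # NB(mean mu, dispersion r): counts ~ NegBin(r, p = r / (r + mu))
    p = nb_dispersion / (nb_dispersion + mu)
    counts = rng.negative_binomial(nb_dispersion, p)
    return counts, gene_ids, truth


def default_covariate_table(
    n_samples: int = 15, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Three-tier neighborhood covariate table (low/mid/high violence).

    Samples split as evenly as possible across tiers; violent crime
    rates (events per 1,000 residents) are drawn uniformly within tier
    ranges low U(1, 6), mid U(8, 16), high U(20, 40) — magnitudes
    plausible for city-level health-atlas zip-code data.  Overall crime,
    poverty and racial/ethnic composition co-vary with tier.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tiers = ["low", "medium", "high"]
    tier = [tiers[min(i * 3 // n_samples, 2)] for i in range(n_samples)]
    lo_hi = {"low": (1.0, 6.0), "medium": (8.0, 16.0), "high": (20.0, 40.0)}
    pov = {"low": (5.0, 15.0), "medium": (10.0, 25.0), "high": (20.0, 40.0)}
    rows = []
    for i, t in enumerate(tier):
        violent = rng.uniform(*lo_hi[t])
        black = rng.uniform(10, 80)
        hisp = rng.uniform(0, 100 - black)
        rows.append(
            {
                "sample_id": f"S{i + 1:02d}",
                "violent_crime_rate": violent,
                "overall_crime_rate": violent * 3.0 + rng.uniform(10, 40),
                "pct_poverty": rng.uniform(*pov[t]),
                "pct_black": black,
                "pct_hispanic": hisp,
                "pct_white": 100.0 - black - hisp,
                "crime_tier": t,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_study(design: StudyDesign):
    """Per-sample mean expression table with covariate-linked genes.

    Returns
    -------
    (means, covariates, truth)
        ``means``: genes x samples DataFrame; ``covariates``: the
        (supplied or generated) covariate table; ``truth``: dict with
        the covariate-linked gene list and the planted slope.
    """
    root = np.random.SeedSequence(design.seed)
    cov_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(2))
    cov = (
        design.covariates.copy()
        if design.covariates is not None
        else default_covariate_table(design.n_samples, cov_rng)
    )
    if len(cov) != design.n_samples:
        raise ValueError("covariate table rows must equal n_samples")
    x = cov["violent_crime_rate"].to_numpy(dtype=float)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(design.n_genes)]
    linked = gene_ids[: design.n_covariate_genes] if design.effect_slope != 0 else []
    slopes = np.zeros(design.n_genes)
    if design.effect_slope != 0:
        slopes[: design.n_covariate_genes] = design.effect_slope
    means = (
        design.baseline
        + slopes[:, None] * x[None, :]
        + noise_rng.normal(0.0, design.noise_sd, size=(design.n_genes, len(x)))
    )
    table = pd.DataFrame(means, index=gene_ids, columns=cov.index)
    truth = {"covariate_genes": linked, "effect_slope": design.effect_slope}
    return table, cov, truth


def _sample_slots(rng, n_slots: int, n_needed: int) -> np.ndarray:
    if n_needed > n_slots:
        raise ValueError(
            f"cannot place {n_needed} non-overlapping peaks in {n_slots} slots; "
            "increase chrom_length or n_chrom"
        )
    return rng.choice(n_slots, size=n_needed, replace=False)


def simulate_peaks(spec: PeakSimSpec):
    """Paired tumor/normal peak sets plus a TSS table.

    Peaks occupy disjoint slots of width ``2 * peak_width`` so records
    never overlap unless shared; shared peaks have identical coordinates
    in both sets.  Exactly ``n_peaks_tumor`` / ``n_peaks_normal``
    records per side and ``round(shared_fraction * min(sides))`` shared
    records.
    """
    from .peaks import PeakSet

    root = np.random.SeedSequence(spec.seed)
    place_rng, score_rng, tss_rng = (np.random.default_rng(s) for s in root.spawn(3))

    n_shared = round(spec.shared_fraction * min(spec.n_peaks_tumor, spec.n_peaks_normal))
    n_t_only = spec.n_peaks_tumor - n_shared
    n_n_only = spec.n_peaks_normal - n_shared

    slot_w = 2 * spec.peak_width
    slots_per_chrom = spec.chrom_length // slot_w
    n_slots = spec.n_chrom * slots_per_chrom
    chosen = _sample_slots(place_rng, n_slots, n_shared + n_t_only + n_n_only)

    def slot_to_interval(slot_ids) -> pd.DataFrame:
        slot_ids = np.asarray(slot_ids)
        chrom = slot_ids // slots_per_chrom
        offset = (slot_ids % slots_per_chrom) * slot_w
        jitter = place_rng.integers(0, slot_w - spec.peak_width, size=len(slot_ids))
        start = offset + jitter
        return pd.DataFrame(
            {
                "chrom": [f"chr{c + 1}" for c in chrom],
                "start": start,
                "end": start + spec.peak_width,
            }
        )

    shared = slot_to_interval(chosen[:n_shared])
    t_only = slot_to_interval(chosen[n_shared : n_shared + n_t_only])
    n_only = slot_to_interval(chosen[n_shared + n_t_only :])

    def build(side_df: pd.DataFrame, prefix: str, shift: float) -> PeakSet:
        df = side_df.copy().reset_index(drop=True)
        df["name"] = [f"{prefix}_{i + 1}" for i in range(len(df))]
        df["enrichment"] = (
            score_rng.normal(spec.score_mean, spec.score_sd, size=len(df)) + shift
        )
        df["strand"] = "."
        return PeakSet(df)

    tumor = build(pd.concat([shared, t_only]), "tumor", spec.enrichment_shift)
    normal = build(pd.concat([shared, n_only]), "normal", 0.0)

    tss = pd.DataFrame(
        {
            "chrom": np.repeat(
                [f"chr{c + 1}" for c in range(spec.n_chrom)], spec.n_tss_per_chrom
            ),
            "tss_position": tss_rng.integers(
                0, spec.chrom_length, size=spec.n_chrom * spec.n_tss_per_chrom
            ),
            "strand": tss_rng.choice(["+", "-"], size=spec.n_chrom * spec.n_tss_per_chrom),
        }
    )
    tss["gene_id"] = [f"TSSGENE{i + 1:04d}" for i in range(len(tss))]
    truth = {
        "n_shared": int(n_shared),
        "shared_intervals": shared.reset_index(drop=True),
        "enrichment_shift": spec.enrichment_shift,
    }
    return tumor, normal, tss, truth
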