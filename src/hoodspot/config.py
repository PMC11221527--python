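"""Declarative pipeline configuration with aggregated validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_PARAMS = {
    "n_perm": 999,
    "alpha_spatial": 0.05,
    "alpha_spatial_strict": 0.01,
    "min_frac": 0.05,           # localized-gene rule: >= 5% of barcodes
    "min_logfc": 0.1,
    "de_alpha": 0.05,
    "corr_alpha": 0.05,
    "covariate": "violent_crime_rate",
    "top_fraction": 0.10,
    "kmeans_k": 7,
    "kmeans_n_init": 10,
    "weights_scheme": "hex_adjacency",
    "knn_k": 6,
    "alternative": "folded",
    "max_moran_genes": 50,      # most-variable genes fed to the Moran scan
    "max_hotspot_genes": 3,     # top localized genes taken to hotspot DE
    "de_rest": "assigned",
}

_RANGES = {
    "alpha_spatial": (0.0, 1.0),
    "alpha_spatial_strict": (0.0, 1.0),
    "min_frac": (0.0, 1.0),
    "de_alpha": (0.0, 1.0),
    "corr_alpha": (0.0, 1.0),
    "top_fraction": (0.0, 1.0),
}


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``samples`` lists per-sample MTX triplet directories and
    tissue-position CSVs; peak paths and the TSS table feed the cistrome
    arm.  ``params`` holds every tunable with documented defaults.
    """

    output_dir: Path
    seed: int = 0
    samples: list[dict] = field(default_factory=list)
    covariates: Path | None = None
    tumor_peaks: Path | None = None
    normal_peaks: Path | None = None
    input_peaks: Path | None = None
    peak_format: str = "bed"
    tss: Path | None = None
    housekeeping: Path | None = None
    params: dict = field(default_factory=dict)

    def canonical(self) -> str:
        d = asdict(self)
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        d["samples"] = [
            {k: str(v) for k, v in s.items()} for s in self.samples
        ]
        return json.dumps(d, sort_keys=True, default=str)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw, base_dir=Path(path).parent)


def validate_config(raw: dict, base_dir: Path | None = None) -> PipelineConfig:
    """Check every constraint before any compute; aggregate all errors."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    problems: list[str] = []

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    def existing(key, p):
        rp = resolve(p)
        if not rp.exists():
            problems.append(f"{key}: path does not exist: {rp}")
        return rp

    if "output_dir" not in raw:
        problems.append("output_dir: required")
    output_dir = resolve(raw.get("output_dir", "hoodspot_run"))

    samples = []
    for i, s in enumerate(raw.get("samples", []) or []):
        sid = s.get("id", f"sample{i + 1}")
        entry = {"id": sid}
        for key in ("counts_dir", "positions"):
            if key not in s:
                problems.append(f"samples[{sid}].{key}: required")
            else:
                entry[key] = existing(f"samples[{sid}].{key}", s[key])
        samples.append(entry)

    paths = {}
    for key in ("covariates", "tumor_peaks", "normal_peaks", "input_peaks",
                "tss", "housekeeping"):
        paths[key] = existing(key, raw[key]) if raw.get(key) else None

    peak_format = raw.get("peak_format", "bed")
    if peak_format not in ("bed", "narrowpeak"):
        problems.append(f"peak_format: must be 'bed' or 'narrowpeak', got {peak_format!r}")

    params = dict(DEFAULT_PARAMS)
    user_params = raw.get("params", {}) or {}
    unknown = sorted(set(user_params) - set(DEFAULT_PARAMS))
    if unknown:
        problems.append(f"params: unknown parameter(s) {unknown}")
    params.update({k: v for k, v in user_params.items() if k in DEFAULT_PARAMS})
    for key, (lo, hi) in _RANGES.items():
        v = params[key]
        if not (lo < v <= hi if key == "top_fraction" else lo < v < hi):
            problems.append(f"params.{key}: {v} outside ({lo}, {hi})")
    if params["n_perm"] < 1:
        problems.append(f"params.n_perm: must be >= 1, got {params['n_perm']}")
    if params["weights_scheme"] not in ("hex_adjacency", "knn"):
        problems.append(f"params.weights_scheme: {params['weights_scheme']!r}")
    if params["de_rest"] not in ("assigned", "all"):
        problems.append(f"params.de_rest: {params['de_rest']!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append(f"seed: must be a non-negative integer, got {seed!r}")

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        samples=samples,
        peak_format=peak_format,
        params=params,
        **paths,
    )
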