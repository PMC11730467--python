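"""Run configuration shared by every pipeline stage.

All analysis thresholds live here so that a single YAML file fully
determines a run: the study year window, the cohort-overlap threshold,
the flock-size threshold (with its sensitivity alternatives), the VIF
cutoff, the AICc averaging window, and the degree-to-metre convention
used when expressing COA trends as displacement in metres per year.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

#: metres per degree of latitude (spherical Earth, mean radius)
METRES_PER_DEGREE = 111_320.0


@dataclasses.dataclass
class RunConfig:
    """Configuration for a centre-of-abundance shift analysis run.

    Parameters
    ----------
    year_start, year_end : int
        Inclusive analysis window; annual survey indices outside it are
        ignored. The default 1970-2019 avoids the sparsely sampled early
        years of both North American surveys.
    overlap_threshold : float
        Cohort overlap index above which (strictly) a species is classed
        as a mixed-age migrant.
    flocking_size_threshold : int
        Maximum travelling flock size above which (strictly) a species
        is classed as a flocking migrant. 2 by default; 5 and 10 are the
        conventional sensitivity settings.
    vif_cutoff : float
        Variance inflation factor above which predictors are removed
        stepwise from the global model.
    aicc_window : float
        Candidate models within this many AICc units of the best model
        enter the averaging set.
    min_samples_per_variable : int
        Candidate models with fewer data rows per predictor column than
        this are excluded to limit overfitting.
    min_banding_records : int
        Minimum total banding records for a species to be classified
        from banding data at all.
    min_records_per_age_class : int
        Minimum records per age class inside the autumn window.
    degree_to_metre : str
        ``"mean_coa"`` converts longitude degrees at the species' mean
        COA latitude (cos-corrected); ``"fixed_ref"`` uses
        ``reference_latitude`` instead (equirectangular sensitivity
        variant); ``"none"`` disables the cos correction entirely.
    overlap_form : str
        ``"min_over_max"`` (default) or ``"min_over_mean"`` for the
        proportional-overlap formula.
    pgls_error_model : str
        ``"additive"`` fits residual covariance sigma^2*C + diag(se^2);
        ``"fixed_weights"`` uses diag(se^2) only (sensitivity variant).
    averaging : str
        ``"full"`` (zero-substituted) or ``"conditional"`` coefficient
        averaging.
    """

    year_start: int = 1970
    year_end: int = 2019
    overlap_threshold: float = 0.85
    flocking_size_threshold: int = 2
    vif_cutoff: float = 5.0
    aicc_window: float = 2.0
    min_samples_per_variable: int = 10
    min_banding_records: int = 1000
    min_records_per_age_class: int = 30
    seed: int = 0
    degree_to_metre: str = "mean_coa"
    reference_latitude: float = 45.0
    overlap_form: str = "min_over_max"
    pgls_error_model: str = "additive"
    averaging: str = "full"
    autumn_eps: float = 0.005
    autumn_min_decline: float = 2.0
    autumn_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.year_start >= self.year_end:
            raise ValueError("year_start must be < year_end")
        for name in ("overlap_threshold", "vif_cutoff", "aicc_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flocking_size_threshold < 1:
            raise ValueError("flocking_size_threshold must be >= 1")
        if self.degree_to_metre not in ("mean_coa", "fixed_ref", "none"):
            raise ValueError(f"unknown degree_to_metre: {self.degree_to_metre}")
        if self.overlap_form not in ("min_over_max", "min_over_mean"):
            raise ValueError(f"unknown overlap_form: {self.overlap_form}")
        if self.pgls_error_model not in ("additive", "fixed_weights"):
            raise ValueError(f"unknown pgls_error_model: {self.pgls_error_model}")
        if self.averaging not in ("full", "conditional"):
            raise ValueError(f"unknown averaging: {self.averaging}")
        if self.autumn_window is not None:
            self.autumn_window = tuple(self.autumn_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["autumn_window"] is not None:
            d["autumn_window"] = list(d["autumn_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        d = dataclasses.asdict(self)
        if d["autumn_window"] is not None:
            d["autumn_window"] = list(d["autumn_window"])
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
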