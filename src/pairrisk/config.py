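"""Pipeline configuration.

All screening thresholds and evaluation settings live in one dataclass so a
single YAML file can drive every stage of the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

DAYS_PER_YEAR = 365.25


@dataclass
class PipelineConfig:
    """Thresholds and settings shared across pipeline stages.

    Parameters
    ----------
    corr_min : float
        Minimum lncRNA/immune-gene correlation for the coexpression screen.
        Applied to the signed coefficient by default (``corr_absolute`` uses
        ``|rho|`` instead).
    corr_p_max : float
        Correlation-test p-value ceiling for the coexpression screen.
    de_fdr_max : float
        Benjamini-Hochberg FDR ceiling for the tumor-vs-normal screen.
    unicox_p_max : float
        Wald p ceiling for the univariate Cox screen over pairs.
    pair_minority_min : float
        Minority-frequency floor for pair retention: the rarer indicator
        value must occur in strictly more than this fraction of samples.
    cv_folds : int
        Folds for the cross-validated lasso Cox path.
    roc_horizons : tuple of float
        Evaluation horizons in years for time-dependent ROC curves.
    time_unit : str
        Unit of the clinical ``time`` column, ``"days"`` or ``"years"``.
        Days are converted to years internally (365.25 d/y).
    corr_tumor_only : bool
        Compute the coexpression screen on tumor samples only (default) or
        on all samples.
    corr_absolute : bool
        Threshold on ``|rho|`` rather than signed rho.
    tie_method : str
        Tie handling in Cox partial likelihoods: ``"breslow"`` or ``"efron"``.
    rng_seed : int
        Seed controlling cross-validation fold assignment.
    """

    corr_min: float = 0.4
    corr_p_max: float = 0.001
    de_fdr_max: float = 0.01
    unicox_p_max: float = 0.01
    pair_minority_min: float = 0.20
    cv_folds: int = 10
    roc_horizons: tuple = (1.0, 2.0, 3.0)
    time_unit: str = "days"
    corr_tumor_only: bool = True
    corr_absolute: bool = False
    tie_method: str = "breslow"
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("corr_min", "corr_p_max", "de_fdr_max", "unicox_p_max",
                     "pair_minority_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v!r}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2; got {self.cv_folds}")
        if self.time_unit not in ("days", "years"):
            raise ValueError(f"time_unit must be 'days' or 'years'; got {self.time_unit!r}")
        if self.tie_method not in ("breslow", "efron"):
            raise ValueError(f"tie_method must be 'breslow' or 'efron'; got {self.tie_method!r}")
        self.roc_horizons = tuple(float(h) for h in self.roc_horizons)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def time_to_years(self, t):
        """Convert a time array in the declared input unit to years."""
        if self.time_unit == "days":
            return t / DAYS_PER_YEAR
        return t
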