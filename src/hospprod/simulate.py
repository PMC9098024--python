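"""Synthetic hospital datasets with the structure the analysis assumes.

The generator emulates a cross-section of county hospitals: one output
(total patient-days, in thousands) and six strictly positive inputs (beds,
materials cost, electricity cost, doctors FTE, nurses FTE, outsourced
services cost; costs in units of 100,000 PLN).  Real hospital inputs are
right-skewed (mean above median in every column) and positively correlated
because they all scale with hospital size.  Both features are produced by a
latent-size factor model on the log scale:

    ln x_k = location_k + loading_k * ln S + eps_k,

with ``ln S ~ N(0, size_log_sd^2)`` a per-hospital latent size shared by all
inputs and ``eps_k`` independent normal idiosyncratic noise.  Output is the
chosen production function evaluated at the inputs times a multiplicative
lognormal disturbance; optionally a fraction of rows receives a gross error
(the log disturbance scaled up) to exercise robust estimation.

The shipped calibration profile reproduces the qualitative shape of the
study population: per-column log-location equal to the log of the observed
median and log-scale chosen so that the lognormal mean/median ratio matches
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .forms import (
    CANONICAL_INPUTS,
    CobbDouglasParams,
    TranslogParams,
    cd_log_design,
    tl_log_design,
)

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "generate_inputs",
    "generate_output",
    "generate_dataset",
    "descriptive_stats",
]

COLUMNS = ("hospital_id", "patient_days") + CANONICAL_INPUTS


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# Log-scale calibration derived from the published descriptive statistics:
# mu = ln(median), sigma = sqrt(2 ln(mean/median)).
_CAL_LOCATION = {
    "beds": 5.4183,
    "materials": 4.0926,
    "electricity": 2.0008,
    "doctors": 4.0254,
    "nurses": 5.2442,
    "services": 4.9229,
}
_CAL_SIGMA = {
    "beds": 0.4352,
    "materials": 0.8559,
    "electricity": 0.7866,
    "doctors": 1.2460,
    "nurses": 1.1878,
    "services": 0.5625,
}

#: Default true technology: Cobb-Douglas over all six inputs with decreasing
#: returns to scale (sum of exponents 0.90), intercept placed so the median
#: output is ~53 thousand patient-days.
_DEFAULT_TRUE_PARAMS = CobbDouglasParams(
    log_alpha0=-0.4165,
    alphas={
        "beds": 0.50,
        "materials": 0.05,
        "electricity": 0.09,
        "doctors": 0.05,
        "nurses": 0.18,
        "services": 0.03,
    },
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the synthetic hospital-data generator.

    Defaults follow the shipped calibration profile (study-population shape,
    n=94 hospitals, log-output noise sd 0.15, no gross outliers).
    """

    n_hospitals: int = 94
    seed: int = 0
    form: str = "cobb_douglas"
    true_params: CobbDouglasParams | TranslogParams = _DEFAULT_TRUE_PARAMS
    input_names: tuple[str, ...] = CANONICAL_INPUTS
    size_log_sd: float = 1.0
    loadings: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.8 * s for k, s in _CAL_SIGMA.items()}
    )
    idiosyncratic_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.6 * s for k, s in _CAL_SIGMA.items()}
    )
    location_log: Mapping[str, float] = field(default_factory=lambda: dict(_CAL_LOCATION))
    noise_log_sd: float = 0.15
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0

    def __post_init__(self) -> None:
        n_par = len(self.true_params.packed())
        if self.n_hospitals < n_par + 2:
            raise ConfigurationError(
                f"n_hospitals={self.n_hospitals} must be >= number of parameters + 2 ({n_par + 2})"
            )
        if self.form not in ("cobb_douglas", "translog"):
            raise ConfigurationError(f"unknown form {self.form!r}")
        if self.size_log_sd < 0 or self.noise_log_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigurationError("outlier_fraction must lie in [0, 1)")
        if self.outlier_scale < 1:
            raise ConfigurationError("outlier_scale must be >= 1")
        for k in self.input_names:
            if self.loadings.get(k, 0.0) <= 0:
                raise ConfigurationError(f"loading for {k!r} must be positive")
            if self.idiosyncratic_log_sd.get(k, 0.0) < 0:
                raise ConfigurationError(f"idiosyncratic sd for {k!r} must be non-negative")

    @classmethod
    def table_calibration(cls, n_hospitals: int = 94, seed: int = 0,
                          **overrides) -> "GeneratorConfig":
        """The calibration profile matching the study population's shape."""
        return cls(n_hospitals=n_hospitals, seed=seed, **overrides)

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


def generate_inputs(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the input table (``n_hospitals`` rows, one column per input).

    Deterministic given ``config.seed``.  Every entry is strictly positive;
    pairwise input correlations are positive in expectation because all
    loadings are positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_hospitals
    ln_size = rng.normal(0.0, config.size_log_sd, size=n)
    cols = {}
    for k in config.input_names:
        eps = rng.normal(0.0, config.idiosyncratic_log_sd.get(k, 0.0), size=n)
        cols[k] = np.exp(config.location_log.get(k, 0.0) + config.loadings[k] * ln_size + eps)
    return pd.DataFrame(cols, columns=list(config.input_names))


def generate_output(
    inputs: pd.DataFrame,
    true_params: CobbDouglasParams | TranslogParams,
    noise_log_sd: float = 0.15,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate patient-days from the production function plus log noise.

    ``ln y = ln f(x) + eta`` with ``eta ~ N(0, noise_log_sd^2)``; a random
    ``outlier_fraction`` of rows has ``eta`` multiplied by ``outlier_scale``.
    Returns ``(patient_days, outlier_mask)``.  The base noise and the outlier
    assignment use the same stream regardless of ``outlier_fraction``, so
    toggling contamination changes only the flagged rows.
    """
    names = true_params.input_names
    X = inputs[list(names)].to_numpy(dtype=float)
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValueError("inputs must be strictly positive and finite")
    if isinstance(true_params, TranslogParams):
        design = np.vstack([tl_log_design(row, names) for row in X])
    else:
        design = np.vstack([cd_log_design(row, names) for row in X])
    log_f = design @ true_params.packed()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    eta = rng.normal(0.0, noise_log_sd, size=len(X))
    u = rng.uniform(size=len(X))
    mask = u < outlier_fraction
    eta = np.where(mask, eta * outlier_scale, eta)
    return np.exp(log_f + eta), mask


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Full synthetic dataset: inputs plus simulated patient-days."""
    inputs = generate_inputs(config)
    y, _ = generate_output(
        inputs,
        config.true_params,
        noise_log_sd=config.noise_log_sd,
        outlier_fraction=config.outlier_fraction,
        outlier_scale=config.outlier_scale,
        seed=config.seed,
    )
    width = len(str(config.n_hospitals))
    ids = [f"H{i + 1:0{width}d}" for i in range(config.n_hospitals)]
    out = pd.DataFrame({"hospital_id": ids, "patient_days": y})
    for k in config.input_names:
        out[k] = inputs[k].to_numpy()
    return out


def descriptive_stats(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-column min / mean / median / max / sd (sample sd, n-1).

    Mirrors the descriptive table layout used for the hospital sample; the
    even-n median is the midpoint of the two central order statistics.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    numeric = dataset.drop(columns=["hospital_id"], errors="ignore")
    stats = pd.DataFrame(
        {
            "min": numeric.min(),
            "mean": numeric.mean(),
            "median": numeric.median(),
            "max": numeric.max(),
            "sd": numeric.std(ddof=1),
        }
    )
    return stats.T
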