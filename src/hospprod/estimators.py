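"""Log-scale estimation of production functions.

Both functional forms are linear in the logs, so fitting reduces to a linear
regression of ln(patient_days) on the form's log design matrix, either by
ordinary least squares or by Huber M-estimation (iteratively reweighted
least squares with tuning constant 1.345 and MAD scale, the conventional
defaults of robust regression software).  Inference is the usual two-sided
t test of each coefficient against zero at ``df = n - p``; residual standard
error is sqrt(RSS / df) on the log-output scale.

The estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) so they
compose with pipelines and model selection.  ``fit_ols`` / ``fit_huber``
are thin wrappers that fit a named model specification on a hospital
dataset and return a serialisable :class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .forms import (
    CANONICAL_INPUTS,
    CobbDouglasParams,
    TranslogParams,
    cd_log_design,
    term_names,
    tl_log_design,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ProductionFunctionRegressor",
    "CobbDouglasRegressor",
    "TranslogRegressor",
    "SingularDesignError",
    "fit_ols",
    "fit_huber",
    "fit_model",
    "count_significant",
]

HUBER_TUNING = 1.345
CONDITION_WARN = 1e8


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (collinear terms)."""


@dataclass(frozen=True)
class ModelSpec:
    """A model to estimate: form, ordered input subset, estimation method."""

    form: str
    inputs: tuple[str, ...]
    method: str = "ols"
    model_id: str | None = None

    def __post_init__(self) -> None:
        if self.form not in ("cobb_douglas", "translog"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.method not in ("ols", "huber"):
            raise ValueError(f"unknown method {self.method!r}")
        inputs = tuple(self.inputs)
        if not 2 <= len(inputs) <= 3:
            raise ValueError("a model uses two or three inputs")
        unknown = [i for i in inputs if i not in CANONICAL_INPUTS]
        if unknown:
            raise ValueError(f"unknown input name(s) {unknown}; choose from {CANONICAL_INPUTS}")
        if len(set(inputs)) != len(inputs):
            raise ValueError("duplicate input names")
        object.__setattr__(self, "inputs", inputs)

    @property
    def label(self) -> str:
        mid = f"{self.model_id}: " if self.model_id else ""
        return f"{mid}{self.form}({', '.join(self.inputs)}) [{self.method}]"


@dataclass
class FitResult:
    """Estimated coefficients and inference for one model specification."""

    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    residual_standard_error: float
    n_obs: int
    df_resid: int
    converged: bool = True
    error: str | None = None
    params: CobbDouglasParams | TranslogParams | None = field(default=None, repr=False)

    @property
    def n_significant_excl_intercept(self) -> int:
        return count_significant(self)

    def to_dict(self) -> dict:
        return {
            "form": self.spec.form,
            "inputs": list(self.spec.inputs),
            "method": self.spec.method,
            "model_id": self.spec.model_id,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "t_stats": self.t_stats,
            "p_values": self.p_values,
            "residual_standard_error": self.residual_standard_error,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "n_significant_excl_intercept": self.n_significant_excl_intercept,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        spec = ModelSpec(form=d["form"], inputs=tuple(d["inputs"]),
                         method=d["method"], model_id=d.get("model_id"))
        res = cls(
            spec=spec,
            coefficients=dict(d["coefficients"]),
            std_errors=dict(d["std_errors"]),
            t_stats=dict(d["t_stats"]),
            p_values=dict(d["p_values"]),
            residual_standard_error=float(d["residual_standard_error"]),
            n_obs=int(d["n_obs"]),
            df_resid=int(d["df_resid"]),
            converged=bool(d.get("converged", True)),
        )
        res.params = _params_from_coefficients(spec, res.coefficients)
        return res


def count_significant(fit: FitResult, alpha: float = 0.05,
                      exclude_intercept: bool = True) -> int:
    """Number of coefficients with p strictly below ``alpha``."""
    items = fit.p_values.items()
    return sum(
        1 for name, p in items
        if p < alpha and not (exclude_intercept and name == "intercept")
    )


def _params_from_coefficients(spec: ModelSpec, coefs: Mapping[str, float]):
    if spec.form == "cobb_douglas":
        return CobbDouglasParams.from_dict({k: coefs[k] for k in coefs})
    return TranslogParams.from_dict({k: coefs[k] for k in coefs})


class ProductionFunctionRegressor(RegressorMixin, BaseEstimator):
    """Production-function regression on the log scale.

    Parameters
    ----------
    form : {"cobb_douglas", "translog"}
        Functional form of the technology.
    method : {"ols", "huber"}
        Ordinary least squares or Huber M-estimation (IRLS with MAD scale
        re-estimated each iteration, max 50 iterations).
    significance_level : float
        Threshold for the per-coefficient t tests (strict inequality).
    huber_t : float
        Huber tuning constant; the conventional 1.345 by default.  As
        ``huber_t`` grows the M-estimator tends to least squares.

    Attributes
    ----------
    params_ : CobbDouglasParams or TranslogParams
        The estimated production function.
    intercept_ : float
        Log-scale intercept.
    coef_ : ndarray
        Non-intercept packed coefficients (term order in ``term_names_``).
    std_errors_, t_stats_, p_values_ : pandas.Series indexed by term name.
    resid_se_ : float
        Residual standard error sqrt(RSS / df_resid) on the log scale.
    converged_ : bool
        Always True for OLS; IRLS convergence flag for Huber.
    """

    def __init__(self, form: str = "cobb_douglas", method: str = "ols",
                 significance_level: float = 0.05, huber_t: float = HUBER_TUNING):
        self.form = form
        self.method = method
        self.significance_level = significance_level
        self.huber_t = huber_t

    # -- helpers -----------------------------------------------------------
    def _design(self, X: np.ndarray) -> np.ndarray:
        builder = cd_log_design if self.form == "cobb_douglas" else tl_log_design
        return np.vstack([builder(row) for row in X])

    def _validate_X_y(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise ValueError("X must be two-dimensional")
            names = [f"x{i + 1}" for i in range(Xv.shape[1])]
        if np.any(Xv <= 0) or not np.all(np.isfinite(Xv)):
            raise ValueError("all inputs must be strictly positive and finite")
        if y is not None:
            yv = np.asarray(y, dtype=float).ravel()
            if len(yv) != len(Xv):
                raise ValueError("X and y have different lengths")
            if np.any(yv <= 0) or not np.all(np.isfinite(yv)):
                raise ValueError("output must be strictly positive and finite")
            return Xv, yv, names
        return Xv, names

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        if self.form not in ("cobb_douglas", "translog"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.method not in ("ols", "huber"):
            raise ValueError(f"unknown method {self.method!r}")
        Xv, yv, names = self._validate_X_y(X, y)
        design = self._design(Xv)
        terms = term_names(names, self.form)
        n, p = design.shape
        if n <= p:
            raise ValueError(f"need more than {p} observations to fit {p} parameters; got {n}")

        rank = np.linalg.matrix_rank(design)
        if rank < p:
            # pivoted QR: the trailing pivots name the redundant terms
            _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
            collinear = [terms[i] for i in piv[rank:]]
            raise SingularDesignError(
                f"design matrix is rank deficient (rank {rank} < {p}); "
                f"collinear term(s): {collinear}"
            )
        # condition number on column-scaled design (the intercept column and
        # raw log scales otherwise dominate the estimate)
        scaled = design / np.linalg.norm(design, axis=0)
        cond = np.linalg.cond(scaled)
        if cond > CONDITION_WARN:
            warnings.warn(
                f"ill-conditioned design (condition number {cond:.3g}); "
                "estimates may be numerically unstable",
                RuntimeWarning,
            )
        self.condition_number_ = float(cond)

        ln_y = np.log(yv)
        if self.method == "ols":
            res = sm.OLS(ln_y, design).fit()
            self.converged_ = True
        else:
            model = sm.RLM(ln_y, design, M=sm.robust.norms.HuberT(t=self.huber_t))
            res = model.fit(maxiter=50, tol=1e-8, scale_est="mad", conv="coefs")
            n_iter = len(res.fit_history.get("params", [])) or res.fit_history.get("iteration", 0)
            self.converged_ = bool(n_iter < 50)
            if not self.converged_:
                warnings.warn("Huber IRLS did not converge within 50 iterations", RuntimeWarning)

        beta = np.asarray(res.params, dtype=float)
        resid = ln_y - design @ beta
        df_resid = n - p
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.term_names_ = terms
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.n_obs_ = n
        self.df_resid_ = df_resid
        self.resid_se_ = float(np.sqrt(resid @ resid / df_resid))
        self.scale_ = float(getattr(res, "scale", self.resid_se_ ** 2))
        self.std_errors_ = pd.Series(np.asarray(res.bse, dtype=float), index=terms)
        self.t_stats_ = pd.Series(np.asarray(res.tvalues, dtype=float), index=terms)
        self.p_values_ = pd.Series(np.asarray(res.pvalues, dtype=float), index=terms)
        coef_map = dict(zip(terms, beta))
        if self.form == "cobb_douglas":
            self.params_ = CobbDouglasParams.from_dict(coef_map)
        else:
            self.params_ = TranslogParams.from_dict(coef_map)
        return self

    def predict(self, X):
        """Predicted output on the raw scale, exp of the log-linear predictor."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        Xv, _ = self._validate_X_y(X)
        design = self._design(Xv)
        beta = np.concatenate(([self.intercept_], self.coef_))
        return np.exp(design @ beta)

    # -- reporting ---------------------------------------------------------
    def n_significant_(self, exclude_intercept: bool = True) -> int:
        pv = self.p_values_
        if exclude_intercept:
            pv = pv.drop("intercept")
        return int((pv < self.significance_level).sum())

    def to_fit_result(self, spec: ModelSpec | None = None) -> FitResult:
        if spec is None:
            spec = ModelSpec(form=self.form, inputs=tuple(self.feature_names_in_),
                             method=self.method)
        return FitResult(
            spec=spec,
            coefficients={t: float(v) for t, v in
                          zip(self.term_names_, np.concatenate(([self.intercept_], self.coef_)))},
            std_errors=self.std_errors_.to_dict(),
            t_stats=self.t_stats_.to_dict(),
            p_values=self.p_values_.to_dict(),
            residual_standard_error=self.resid_se_,
            n_obs=self.n_obs_,
            df_resid=self.df_resid_,
            converged=self.converged_,
            params=self.params_,
        )


class CobbDouglasRegressor(ProductionFunctionRegressor):
    """Cobb-Douglas production-function regression."""

    def __init__(self, method: str = "ols", significance_level: float = 0.05,
                 huber_t: float = HUBER_TUNING):
        super().__init__(form="cobb_douglas", method=method,
                         significance_level=significance_level, huber_t=huber_t)


class TranslogRegressor(ProductionFunctionRegressor):
    """Translog production-function regression."""

    def __init__(self, method: str = "ols", significance_level: float = 0.05,
                 huber_t: float = HUBER_TUNING):
        super().__init__(form="translog", method=method,
                         significance_level=significance_level, huber_t=huber_t)


def fit_model(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit ``spec`` on a hospital dataset (patient_days on the spec's inputs)."""
    est = ProductionFunctionRegressor(form=spec.form, method=spec.method)
    est.fit(dataset[list(spec.inputs)], dataset["patient_days"])
    return est.to_fit_result(spec)


def fit_ols(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary-least-squares fit of ``spec`` regardless of ``spec.method``."""
    return fit_model(dataset, ModelSpec(spec.form, spec.inputs, "ols", spec.model_id))


def fit_huber(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Huber robust fit of ``spec`` regardless of ``spec.method``."""
    return fit_model(dataset, ModelSpec(spec.form, spec.inputs, "huber", spec.model_id))
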