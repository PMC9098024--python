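"""Derived economics of a fitted production function.

Given a production function f and a raw-scale evaluation point x, the
quantities of managerial interest are

* elasticity        E_i = d ln f / d ln x_i  (% output per 1% of input i);
  for Cobb-Douglas this is the exponent alpha_i, independent of x; for the
  translog  E_k = a_k + 2 b_kk ln x_k + sum_{l != k} b_kl ln x_l;
* marginal product  T_i = df/dx_i = E_i * f(x) / x_i  (output units per one
  raw unit of input i, other inputs held fixed);
* growth rate       S_i = T_i / f(x) = E_i / x_i  (relative output change
  per raw unit of input i);
* returns to scale  RTS = sum_i E_i  (% output per 1% increase in *all*
  inputs; the scale elasticity d ln f(lambda x)/d ln lambda at lambda=1);
* MRTS              sigma_ij = T_i / T_j = (E_i/E_j) (x_j/x_i)  (units of
  input j replacing one unit of input i at constant output);
* percent substitution  E_i/E_j  (% of input j replacing 1% of input i
  along the isoquant);
* elasticity of substitution — identically 1 for Cobb-Douglas (the input
  ratio moves one-for-one with the MRTS along an isoquant).

A rational producer operates where every elasticity (hence every marginal
product) is non-negative; a fitted model violating this at the evaluation
point is flagged invalid, naming the offending inputs.

All evaluations use the model-fitted output level f(x), not the sample mean
of observed output, so the identity chain T_i = E_i f/x_i = S_i f holds
exactly.  Growth rates are returned as raw proportions; the reporting layer
may label them as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .forms import (
    CobbDouglasParams,
    TranslogParams,
    cd_value,
    tl_value,
    validate_input_vector,
)

__all__ = [
    "EconomicProfile",
    "UnsupportedFormError",
    "UndefinedSubstitutionError",
    "fitted_output",
    "elasticities",
    "marginal_products",
    "growth_rates",
    "returns_to_scale",
    "mrts",
    "percent_substitution",
    "substitution_elasticity",
    "validity_flags",
    "economic_profile",
]

Params = CobbDouglasParams | TranslogParams


class UnsupportedFormError(NotImplementedError):
    """Requested quantity has no closed form for this functional form."""


class UndefinedSubstitutionError(ZeroDivisionError):
    """Substitution measure undefined: denominator elasticity is zero."""


def fitted_output(params: Params, x: Mapping[str, float]) -> float:
    """Model output level f(x) at the raw-scale point ``x``."""
    if isinstance(params, TranslogParams):
        return tl_value(params, x)
    return cd_value(params, x)


def elasticities(params: Params, x: Mapping[str, float]) -> pd.Series:
    """Output elasticity of each input at ``x`` (CD: the exponents)."""
    names = params.input_names
    vals = validate_input_vector(x, names)
    if isinstance(params, CobbDouglasParams):
        return pd.Series({n: float(params.alphas[n]) for n in names})
    lx = dict(zip(names, np.log(vals)))
    out = {}
    for k in names:
        e = params.linear[k] + 2.0 * params.quad_coef(k, k) * lx[k]
        e += sum(params.quad_coef(k, l) * lx[l] for l in names if l != k)
        out[k] = float(e)
    return pd.Series(out)


def marginal_products(params: Params, x: Mapping[str, float]) -> pd.Series:
    """Marginal product of each input: T_i = E_i * f(x) / x_i."""
    E = elasticities(params, x)
    f = fitted_output(params, x)
    return pd.Series({n: float(E[n] * f / float(x[n])) for n in params.input_names})


def growth_rates(params: Params, x: Mapping[str, float]) -> pd.Series:
    """Production growth rate S_i = T_i / f(x) = E_i / x_i (raw proportion)."""
    E = elasticities(params, x)
    return pd.Series({n: float(E[n] / float(x[n])) for n in params.input_names})


def returns_to_scale(params: Params, x: Mapping[str, float]) -> float:
    """Scale elasticity: the sum of the input elasticities at ``x``."""
    return float(elasticities(params, x).sum())


def mrts(params: Params, x: Mapping[str, float], i: str, j: str) -> float:
    """Marginal rate of technical substitution sigma_ij = T_i / T_j.

    Units of input j needed to replace one raw unit of input i at constant
    output; equals (E_i/E_j)(x_j/x_i).
    """
    E = elasticities(params, x)
    if E[j] == 0:
        raise UndefinedSubstitutionError(
            f"MRTS({i},{j}) undefined: elasticity of {j!r} is zero"
        )
    return float((E[i] / E[j]) * (float(x[j]) / float(x[i])))


def percent_substitution(params: Params, x: Mapping[str, float], i: str, j: str) -> float:
    """Percent-for-percent substitution E_i/E_j along the isoquant."""
    E = elasticities(params, x)
    if E[j] == 0:
        raise UndefinedSubstitutionError(
            f"percent substitution ({i},{j}) undefined: elasticity of {j!r} is zero"
        )
    return float(E[i] / E[j])


def substitution_elasticity(params: Params, x: Mapping[str, float] | None = None,
                            i: str | None = None, j: str | None = None) -> float:
    """Elasticity of substitution between two inputs.

    Closed form only for Cobb-Douglas, where it equals 1 for every input
    pair and every evaluation point.  Not computed for the translog.
    """
    if isinstance(params, TranslogParams):
        raise UnsupportedFormError(
            "the elasticity of substitution is only reported in closed form "
            "for the Cobb-Douglas model (where it is identically 1)"
        )
    return 1.0


def validity_flags(E: pd.Series) -> tuple[bool, list[str]]:
    """Production-function validity at the evaluation point.

    Valid iff every elasticity (equivalently every marginal product, since
    f(x)/x_i > 0) is non-negative; returns the offending inputs otherwise.
    """
    violations = [str(n) for n in E.index if E[n] < 0]
    return (len(violations) == 0, violations)


@dataclass
class EconomicProfile:
    """All derived economics of one model at one evaluation point."""

    label: str
    x: dict[str, float]
    fitted_output: float
    elasticities: pd.Series
    marginal_products: pd.Series
    growth_rates: pd.Series
    returns_to_scale: float
    mrts: pd.DataFrame
    percent_substitution: pd.DataFrame
    substitution_elasticity_cd: float | None
    valid_production_function: bool
    violations: list[str]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "evaluation_point": self.x,
            "fitted_output": self.fitted_output,
            "elasticities": self.elasticities.to_dict(),
            "marginal_products": self.marginal_products.to_dict(),
            "growth_rates": self.growth_rates.to_dict(),
            "returns_to_scale": self.returns_to_scale,
            "mrts": {f"{i}->{j}": float(self.mrts.loc[i, j])
                     for i in self.mrts.index for j in self.mrts.columns if i != j},
            "percent_substitution": {
                f"{i}->{j}": float(self.percent_substitution.loc[i, j])
                for i in self.percent_substitution.index
                for j in self.percent_substitution.columns if i != j},
            "substitution_elasticity_cd": self.substitution_elasticity_cd,
            "valid_production_function": self.valid_production_function,
            "violations": self.violations,
        }


def economic_profile(params: Params, x: Mapping[str, float],
                     label: str = "custom") -> EconomicProfile:
    """Evaluate every derived quantity of ``params`` at the point ``x``."""
    names = list(params.input_names)
    E = elasticities(params, x)
    f = fitted_output(params, x)
    T = marginal_products(params, x)
    S = growth_rates(params, x)
    rts = float(E.sum())

    sig = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    pct = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            if i == j:
                sig.loc[i, j] = 1.0 if E[i] != 0 else np.nan
                pct.loc[i, j] = 1.0 if E[i] != 0 else np.nan
            elif E[j] != 0:
                sig.loc[i, j] = (E[i] / E[j]) * (float(x[j]) / float(x[i]))
                pct.loc[i, j] = E[i] / E[j]

    valid, violations = validity_flags(E)
    eps_cd = 1.0 if isinstance(params, CobbDouglasParams) else None
    return EconomicProfile(
        label=label,
        x={n: float(x[n]) for n in names},
        fitted_output=f,
        elasticities=E,
        marginal_products=T,
        growth_rates=S,
        returns_to_scale=rts,
        mrts=sig,
        percent_substitution=pct,
        substitution_elasticity_cd=eps_cd,
        valid_production_function=valid,
        violations=violations,
    )
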