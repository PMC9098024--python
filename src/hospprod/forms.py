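"""Production-function forms: Cobb-Douglas and translog.

Both forms are linear in the logarithms of the inputs, which is what makes
ordinary least squares on log output the natural estimator.  A Cobb-Douglas
function

    y = alpha0 * prod_i x_i ** alpha_i

has log form  ln y = ln(alpha0) + sum_i alpha_i ln x_i,  and the exponent
``alpha_i`` is the (input-independent) output elasticity of input i.  The
translog generalises it by adding squared and cross log terms:

    ln y = a0 + sum_k a_k ln x_k
              + sum_k b_kk (ln x_k)^2
              + sum_{k<l} b_kl ln x_k ln x_l

and collapses back to Cobb-Douglas when every quadratic coefficient is zero.

Packed parameter / design-row term ordering is fixed and shared by both the
estimators and the serialisation layer: intercept first, then the linear
log terms in input order, then the squared log terms in input order, then
the cross terms in lexicographic pair order.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CANONICAL_INPUTS",
    "CobbDouglasParams",
    "TranslogParams",
    "cd_value",
    "cd_log_value",
    "cd_log_design",
    "tl_value",
    "tl_log_value",
    "tl_log_design",
    "term_names",
    "validate_input_vector",
]

#: Canonical input order for the hospital dataset (matches the CSV layout).
CANONICAL_INPUTS: tuple[str, ...] = (
    "beds",
    "materials",
    "electricity",
    "doctors",
    "nurses",
    "services",
)


class DomainError(ValueError):
    """Raised for non-positive inputs or mismatched input names."""


def validate_input_vector(x: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    """Return ``x`` as an array ordered by ``names``, enforcing positivity."""
    missing = [n for n in names if n not in x]
    if missing:
        raise DomainError(f"input vector missing entries for {missing}")
    vals = np.asarray([float(x[n]) for n in names], dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        bad = [n for n, v in zip(names, vals) if not (np.isfinite(v) and v > 0)]
        raise DomainError(f"inputs must be strictly positive and finite; offending: {bad}")
    return vals


@dataclass(frozen=True)
class CobbDouglasParams:
    """Cobb-Douglas parameters on the log scale.

    Parameters
    ----------
    log_alpha0 : float
        Intercept ln(alpha0).
    alphas : mapping of input name -> exponent
        The output elasticities; order of ``input_names`` is authoritative.
    """

    log_alpha0: float
    alphas: Mapping[str, float]

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(self.alphas.keys())

    def packed(self) -> np.ndarray:
        """Packed coefficient vector ``[intercept, alpha_1, ..., alpha_m]``."""
        return np.concatenate(([self.log_alpha0], list(self.alphas.values())))

    def to_dict(self) -> dict[str, float]:
        out = {"intercept": float(self.log_alpha0)}
        out.update({f"ln_{n}": float(a) for n, a in self.alphas.items()})
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CobbDouglasParams":
        alphas = {k[3:]: float(v) for k, v in d.items() if k.startswith("ln_") and "^" not in k and "*" not in k}
        return cls(log_alpha0=float(d["intercept"]), alphas=alphas)


@dataclass(frozen=True)
class TranslogParams:
    """Translog parameters with a symmetric quadratic block.

    ``quad`` is keyed by ordered pairs ``(i, j)`` with i appearing no later
    than j in the model's input order; diagonal entries are the squared-log
    coefficients, off-diagonal entries the (single-counted) cross-term
    coefficients.
    """

    intercept: float
    linear: Mapping[str, float]
    quad: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.linear.keys())
        order = {n: k for k, n in enumerate(names)}
        canon: dict[tuple[str, str], float] = {}
        for (i, j), b in self.quad.items():
            if i not in order or j not in order:
                raise DomainError(f"quad key ({i},{j}) not among inputs {names}")
            key = (i, j) if order[i] <= order[j] else (j, i)
            if key in canon and not np.isclose(canon[key], float(b)):
                raise DomainError(f"asymmetric quadratic coefficients for pair {key}")
            canon[key] = float(b)
        object.__setattr__(self, "quad", canon)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(self.linear.keys())

    def quad_coef(self, i: str, j: str) -> float:
        order = {n: k for k, n in enumerate(self.input_names)}
        key = (i, j) if order[i] <= order[j] else (j, i)
        return float(self.quad.get(key, 0.0))

    def packed(self) -> np.ndarray:
        names = self.input_names
        vec = [self.intercept]
        vec += [self.linear[n] for n in names]
        vec += [self.quad_coef(n, n) for n in names]
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                vec.append(self.quad_coef(names[a], names[b]))
        return np.asarray(vec, dtype=float)

    def to_dict(self) -> dict[str, float]:
        names = self.input_names
        out = {"intercept": float(self.intercept)}
        out.update({f"ln_{n}": float(self.linear[n]) for n in names})
        out.update({f"ln_{n}^2": self.quad_coef(n, n) for n in names})
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                out[f"ln_{names[a]}*ln_{names[b]}"] = self.quad_coef(names[a], names[b])
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TranslogParams":
        linear = {k[3:]: float(v) for k, v in d.items()
                  if k.startswith("ln_") and "^" not in k and "*" not in k}
        quad: dict[tuple[str, str], float] = {}
        for k, v in d.items():
            if k.endswith("^2"):
                quad[(k[3:-2], k[3:-2])] = float(v)
            elif "*" in k:
                a, b = k.split("*")
                quad[(a[3:], b[3:])] = float(v)
        return cls(intercept=float(d["intercept"]), linear=linear, quad=quad)


def term_names(input_names: Sequence[str], form: str) -> list[str]:
    """Names of the packed coefficient vector for ``form`` over ``input_names``."""
    names = list(input_names)
    terms = ["intercept"] + [f"ln_{n}" for n in names]
    if form == "translog":
        terms += [f"ln_{n}^2" for n in names]
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                terms.append(f"ln_{names[a]}*ln_{names[b]}")
    elif form != "cobb_douglas":
        raise ValueError(f"unknown form {form!r}")
    return terms


def cd_log_design(x: Mapping[str, float] | np.ndarray,
                  names: Sequence[str] | None = None) -> np.ndarray:
    """Design row ``[1, ln x_1, ..., ln x_m]`` for the log-linear fit."""
    if isinstance(x, Mapping):
        vals = validate_input_vector(x, list(x.keys()) if names is None else names)
    else:
        vals = _check_pos(x)
    return np.concatenate(([1.0], np.log(vals)))


def _check_pos(vals: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(vals), dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DomainError("inputs must be strictly positive and finite")
    return arr


def tl_log_design(x: Mapping[str, float] | np.ndarray,
                  names: Sequence[str] | None = None) -> np.ndarray:
    """Translog design row: ``[1, ln x, (ln x)^2, cross products]``.

    Length is ``1 + m + m(m+1)/2``; each off-diagonal pair appears once.
    """
    if isinstance(x, Mapping):
        vals = validate_input_vector(x, list(x.keys()) if names is None else names)
    else:
        vals = _check_pos(x)
    lx = np.log(vals)
    m = len(lx)
    cross = [lx[a] * lx[b] for a in range(m) for b in range(a + 1, m)]
    return np.concatenate(([1.0], lx, lx ** 2, cross))


def cd_log_value(params: CobbDouglasParams, x: Mapping[str, float]) -> float:
    """ln f(x) for the Cobb-Douglas form."""
    names = params.input_names
    row = cd_log_design(x, names)
    return float(row @ params.packed())


def cd_value(params: CobbDouglasParams, x: Mapping[str, float]) -> float:
    """f(x) = alpha0 * prod x_i^alpha_i."""
    return float(np.exp(cd_log_value(params, x)))


def tl_log_value(params: TranslogParams, x: Mapping[str, float]) -> float:
    """ln f(x) for the translog form."""
    names = params.input_names
    row = tl_log_design(x, names)
    return float(row @ params.packed())


def tl_value(params: TranslogParams, x: Mapping[str, float]) -> float:
    """Translog production level at the raw-scale input vector ``x``."""
    return float(np.exp(tl_log_value(params, x)))
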