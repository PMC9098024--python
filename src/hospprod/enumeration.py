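"""Model-space enumeration, batch fitting and per-input comparison tables.

The model space is every two- or three-element subset of the six inputs
(beds, materials, electricity, doctors, nurses, services) that contains at
least one of the core capacity/staffing factors — beds, doctors or nurses.
That leaves 12 admissible pairs (15 minus the 3 all-cost pairs) and 19
admissible triples (20 minus the single all-cost triple).  Specs are
numbered M1, M2, ... in lexicographic subset order over the canonical input
order, so identifiers are stable across runs.

Fits are compared per explanatory variable: for each input, aggregate the
residual standard error (median/min/max) and the number of significant
non-intercept coefficients (mean/median) over exactly the fitted models
whose specification contains that input.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import FitResult, ModelSpec, fit_model
from .forms import CANONICAL_INPUTS

__all__ = [
    "CORE_INPUTS",
    "enumerate_specs",
    "fit_all",
    "compare_by_input",
    "filter_subsample",
    "BatchError",
    "EmptySubsampleError",
]

log = logging.getLogger(__name__)

CORE_INPUTS = ("beds", "doctors", "nurses")


class BatchError(RuntimeError):
    """Every specification in a batch failed to fit."""


class EmptySubsampleError(ValueError):
    """A subsample filter removed every hospital."""


def enumerate_specs(form: str, size: int, method: str = "ols",
                    all_inputs: Sequence[str] = CANONICAL_INPUTS,
                    core_inputs: Sequence[str] = CORE_INPUTS) -> list[ModelSpec]:
    """All admissible ``size``-input specs, numbered M1.. in subset order."""
    if size not in (2, 3):
        raise ValueError("model size must be 2 or 3")
    specs = []
    for combo in combinations(all_inputs, size):
        if any(c in core_inputs for c in combo):
            specs.append(combo)
    return [
        ModelSpec(form=form, inputs=combo, method=method, model_id=f"M{k + 1}")
        for k, combo in enumerate(specs)
    ]


def fit_all(dataset: pd.DataFrame, specs: Iterable[ModelSpec]) -> list[FitResult]:
    """Fit every spec; individual failures are recorded, not fatal."""
    results: list[FitResult] = []
    n_failed = 0
    for spec in specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                results.append(fit_model(dataset, spec))
        except Exception as exc:  # noqa: BLE001 - batch isolation is the point
            n_failed += 1
            log.warning("fit failed for %s: %s", spec.label, exc)
            results.append(FitResult(
                spec=spec, coefficients={}, std_errors={}, t_stats={},
                p_values={}, residual_standard_error=float("nan"),
                n_obs=len(dataset), df_resid=0, converged=False, error=str(exc),
            ))
    if results and n_failed == len(results):
        raise BatchError("every model specification failed to fit")
    return results


def compare_by_input(fits: Sequence[FitResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-input aggregation of fit quality over the models containing it.

    Rows are input names; columns median/min/max residual standard error and
    mean/median number of significant non-intercept coefficients.
    """
    ok = [f for f in fits if f.error is None and np.isfinite(f.residual_standard_error)]
    if not ok:
        raise ValueError("no successful fits to compare")
    rows = {}
    for name in CANONICAL_INPUTS:
        containing = [f for f in ok if name in f.spec.inputs]
        if not containing:
            log.warning("input %r appears in no fitted model; omitted", name)
            continue
        rse = np.array([f.residual_standard_error for f in containing])
        nsig = np.array([
            sum(1 for t, p in f.p_values.items() if t != "intercept" and p < alpha)
            for f in containing
        ], dtype=float)
        rows[name] = {
            "median_rse": float(np.median(rse)),
            "min_rse": float(rse.min()),
            "max_rse": float(rse.max()),
            "mean_n_significant": float(nsig.mean()),
            "median_n_significant": float(np.median(nsig)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def filter_subsample(dataset: pd.DataFrame,
                     beds_iqr: bool = True,
                     flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Restrict to mid-sized hospitals and optional boolean attributes.

    ``beds_iqr`` keeps hospitals whose bed count lies between the first and
    third quartile of the sample, inclusive (quartiles by linear
    interpolation of order statistics).  ``flags`` filters on boolean-valued
    columns when present (e.g. ``{"public": True, "has_ED": True}``).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    keep = pd.Series(True, index=dataset.index)
    if beds_iqr:
        q1, q3 = np.quantile(dataset["beds"].to_numpy(dtype=float), [0.25, 0.75])
        keep &= dataset["beds"].between(q1, q3)
    for col, wanted in (flags or {}).items():
        if col not in dataset.columns:
            raise KeyError(f"filter column {col!r} not present in dataset")
        keep &= dataset[col].astype(bool) == wanted
    out = dataset.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise EmptySubsampleError("subsample filter removed every hospital")
    return out
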