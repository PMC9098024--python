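"""End-to-end pipeline: simulate/load -> batch fit -> profile -> compare.

Produces a report bundle on disk: dataset descriptives, every fit, economic
profiles at the sample means and medians for every model that satisfies the
production-function validity conditions, per-input comparison tables, and
(optionally) the mid-sized-hospital subsample comparison.  Every artifact
is stamped with the seed and a hash of the configuration, since the study
this mirrors is otherwise non-reproducible without its private data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import economics
from .data import read_csv, write_csv
from .economics import EconomicProfile, economic_profile
from .enumeration import compare_by_input, enumerate_specs, filter_subsample, fit_all
from .estimators import FitResult
from .simulate import GeneratorConfig, descriptive_stats, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "render_profile_narrative", "evaluation_points"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str | Path
    data_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    forms: tuple[str, ...] = ("cobb_douglas", "translog")
    sizes: tuple[int, ...] = (2, 3)
    method: str = "ols"
    significance_level: float = 0.05
    subsample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.significance_level < 1:
            raise ValueError("significance level must lie in (0, 1)")
        if self.data_path is None and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps({
            "data_path": str(self.data_path) if self.data_path else None,
            "generator": repr(self.generator),
            "forms": self.forms, "sizes": self.sizes, "method": self.method,
            "alpha": self.significance_level, "subsample": self.subsample,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def evaluation_points(dataset: pd.DataFrame,
                      inputs: tuple[str, ...]) -> dict[str, dict[str, float]]:
    """Component-wise raw-scale means and medians of the estimation sample."""
    sub = dataset[list(inputs)]
    return {
        "means": sub.mean().to_dict(),
        "medians": sub.median().to_dict(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the bundle also written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    try:
        if config.data_path is not None:
            dataset = read_csv(config.data_path)
        else:
            dataset = generate_dataset(config.generator)
            write_csv(dataset, out / "dataset.csv")
    except Exception as exc:
        raise RuntimeError(f"[stage: data] {exc}") from exc
    log.info("dataset: %d hospitals", len(dataset))

    stats = descriptive_stats(dataset)
    stats.to_csv(out / "descriptives.csv")

    bundle: dict = {"stamp": stamp, "n_hospitals": len(dataset), "fits": [],
                    "profiles": [], "comparisons": {}}
    all_fits: dict[tuple[str, int], list[FitResult]] = {}
    for form in config.forms:
        for size in config.sizes:
            try:
                specs = enumerate_specs(form, size, config.method)
                fits = fit_all(dataset, specs)
            except Exception as exc:
                raise RuntimeError(f"[stage: fit {form} size {size}] {exc}") from exc
            all_fits[(form, size)] = fits
            for fit in fits:
                bundle["fits"].append(fit.to_dict() | stamp)
                if fit.error is not None:
                    continue
                for label, x in evaluation_points(dataset, fit.spec.inputs).items():
                    prof = economic_profile(fit.params, x, label=label)
                    bundle["profiles"].append(
                        {"model": fit.spec.label, "form": form, "size": size}
                        | prof.to_dict() | stamp
                    )
            table = compare_by_input(fits, alpha=config.significance_level)
            key = f"{form}_{size}inputs"
            table.to_csv(out / f"comparison_{key}.csv")
            bundle["comparisons"][key] = table.to_dict(orient="index")

    if config.subsample:
        try:
            sub = filter_subsample(dataset)
        except Exception as exc:
            raise RuntimeError(f"[stage: subsample] {exc}") from exc
        bundle["subsample_n"] = len(sub)
        for (form, size) in all_fits:
            specs = enumerate_specs(form, size, "ols")
            table = compare_by_input(fit_all(sub, specs),
                                     alpha=config.significance_level)
            key = f"subsample_{form}_{size}inputs"
            table.to_csv(out / f"comparison_{key}.csv")
            bundle["comparisons"][key] = table.to_dict(orient="index")

    with open(out / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle


_UNITS = {
    "beds": "bed", "doctors": "doctor FTE", "nurses": "nurse FTE",
    "materials": "100,000 PLN of materials",
    "electricity": "100,000 PLN of electricity",
    "services": "100,000 PLN of outsourced services",
}


def render_profile_narrative(profile: EconomicProfile) -> str:
    """Plain-language, unit-annotated reading of an economic profile.

    Every number in the text is a field of the profile (no re-computation);
    all statements carry the ceteris-paribus qualifier.
    """
    lines = [f"Evaluation at the sample {profile.label} "
             f"(fitted output {profile.fitted_output:.6g} thousand patient-days)."]
    for n in profile.elasticities.index:
        unit = _UNITS.get(n, n)
        lines.append(
            f"Raising {n} by one {unit} changes output by "
            f"{profile.marginal_products[n]:.6g} thousand patient-days "
            f"({profile.growth_rates[n]:.6g} as a proportion of output), "
            "other inputs unchanged."
        )
        lines.append(
            f"A one-percent increase in {n} changes output by "
            f"{profile.elasticities[n]:.6g} percent, other inputs unchanged."
        )
    lines.append(
        f"Raising every input by one percent changes output by "
        f"{profile.returns_to_scale:.6g} percent (returns to scale)."
    )
    names = list(profile.elasticities.index)
    for i in names:
        for j in names:
            if i != j and pd.notna(profile.mrts.loc[i, j]):
                lines.append(
                    f"Replacing one {_UNITS.get(i, i)} requires "
                    f"{profile.mrts.loc[i, j]:.6g} additional {_UNITS.get(j, j)} "
                    "at constant output, other inputs unchanged."
                )
    if profile.substitution_elasticity_cd is not None:
        lines.append(
            "For this Cobb-Douglas model the elasticities are independent of "
            "the evaluation point and the elasticity of substitution equals "
            f"{profile.substitution_elasticity_cd:.6g} for every input pair."
        )
    if not profile.valid_production_function:
        lines.append(
            "Warning: the fitted function violates the producer-rationality "
            "assumptions at this point (negative elasticity, hence negative "
            f"marginal product) for: {', '.join(profile.violations)}. This "
            "signals an inefficient combination of the employed inputs."
        )
    return "\n".join(lines)
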