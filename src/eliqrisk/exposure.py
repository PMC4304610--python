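"""Monte-Carlo / Latin-Hypercube propagation of the exposure formula.

Daily exposure of an e-cigarette user to an agent is modelled as

    exposure [mg/kg bw/day] = c * a * (v / 100) / bw

with c the liquid concentration (mg/ml after unit conversion), a the liquid
amount consumed per day (ml/day), v the vaporization percentage and bw the
bodyweight (kg).  The four inputs are sampled independently; with LHS each
input gets its own independently permuted stratification, which preserves
marginal stratification while leaving the joint draws independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample

__all__ = [
    "ExposureModel",
    "SimulationResult",
    "convert_concentration",
    "simulate",
    "summarize",
    "CONCENTRATION_UNITS",
    "LIQUID_DENSITY_G_PER_ML",
]

#: Assumed liquid density for converting g/100 g mass fractions to mg/ml.
LIQUID_DENSITY_G_PER_ML = 1.0

CONCENTRATION_UNITS = ("mg/ml", "g/100g", "mg/L")


def convert_concentration(
    value, unit: str, density: float = LIQUID_DENSITY_G_PER_ML
):
    """Convert a concentration to mg per ml of liquid.

    ``g/100g`` is a mass fraction: x g/100 g * density g/ml * 1000 mg/g
    / 100 = 10 * x * density mg/ml.
    """
    unit = unit.replace(" ", "")
    if unit == "mg/ml":
        return value
    if unit in ("g/100g", "g/100 g"):
        return np.asarray(value) * 10.0 * density if np.ndim(value) else value * 10.0 * density
    if unit == "mg/L":
        return np.asarray(value) * 1e-3 if np.ndim(value) else value * 1e-3
    raise ValueError(f"unsupported concentration unit {unit!r}")


@dataclass(frozen=True)
class ExposureModel:
    """The four input risk functions plus the concentration unit."""

    agent: str
    concentration: DistributionSpec
    concentration_unit: str
    liquid_amount_per_day: DistributionSpec  # ml/day
    vaporization_percentage: DistributionSpec  # %
    bodyweight: DistributionSpec  # kg

    def __post_init__(self) -> None:
        if self.concentration_unit.replace(" ", "") not in CONCENTRATION_UNITS:
            raise ValueError(
                f"concentration unit must be one of {CONCENTRATION_UNITS}"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Per-iteration input draws and exposures.

    ``draws`` columns: concentration (original unit), amount, vaporization,
    bodyweight, exposure (mg/kg bw/day).
    """

    agent: str
    draws: pd.DataFrame
    n_iterations: int
    seed: int
    method: str

    @property
    def exposures(self) -> np.ndarray:
        return self.draws["exposure"].to_numpy()


def simulate(
    model: ExposureModel,
    n_iterations: int = 10_000,
    seed: int = 0,
    method: str = "lhs",
) -> SimulationResult:
    """Run the Monte-Carlo exposure simulation.

    Each input draws from an independent child stream of ``seed`` so the
    result is reproducible and inputs remain mutually independent.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    children = np.random.SeedSequence(seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in children]
    c = sample(model.concentration, n_iterations, rngs[0], method)
    a = sample(model.liquid_amount_per_day, n_iterations, rngs[1], method)
    v = sample(model.vaporization_percentage, n_iterations, rngs[2], method)
    bw = sample(model.bodyweight, n_iterations, rngs[3], method)
    c_mgml = convert_concentration(c, model.concentration_unit)
    exposure = c_mgml * a * (v / 100.0) / bw
    draws = pd.DataFrame(
        {
            "concentration": c,
            "amount": a,
            "vaporization": v,
            "bodyweight": bw,
            "exposure": exposure,
        }
    )
    return SimulationResult(
        agent=model.agent,
        draws=draws,
        n_iterations=n_iterations,
        seed=seed,
        method=method,
    )


def summarize(result: SimulationResult) -> dict:
    """Mean, SD, median and 5th/95th percentiles of the exposure vector.

    Quantiles use the inverse-ECDF (type 1) definition.
    """
    x = result.exposures
    if x.size == 0:
        raise ValueError("empty simulation result")
    q = np.quantile(x, [0.05, 0.5, 0.95], method="inverted_cdf")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(q[1]),
        "p5": float(q[0]),
        "p95": float(q[2]),
    }
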