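"""Margin-of-exposure (MOE) computation and risk-band classification.

The MOE is the ratio of a toxicological reference point (BMDL, NOAEL, NOEL
or LOAEL, in mg/kg bw/day) to the estimated intake of the same agent.
Computed per simulation iteration it yields an MOE distribution; iterations
with zero exposure (non-use draws of sparsely occurring agents) give an
infinite MOE, which is kept so that the percentiles reflect the full
population of scenarios.

Interpretation bands follow regulatory convention and depend on whether the
reference point comes from animal or human data.  Animal endpoints carry
the default 100-fold uncertainty factor (10 interspecies x 10 intraspecies):
median MOE < 10 is "high risk", < 100 "risk", otherwise "acceptable".  For
human endpoints the interspecies factor drops out: < 1 "high risk", < 10
"risk", otherwise "acceptable".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["ToxThreshold", "MOEResult", "moe_distribution", "categorize"]

ENDPOINT_TYPES = ("LOAEL", "NOAEL", "BMDL10", "NOEL")
MOE_PERCENTILES = (1, 5, 25, 50, 75, 95, 99)


@dataclass(frozen=True)
class ToxThreshold:
    """A toxicological reference point for one agent.

    ``value`` is the primary threshold used for the MOE; ``secondary_value``
    is an ADI or MRL retained only for guidance-value comparisons.
    """

    agent: str
    value: float  # mg/kg bw/day
    endpoint_type: str
    endpoint_source: str  # "human" | "animal"
    secondary_value: Optional[float] = None
    secondary_type: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("threshold value must be positive")
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ValueError(f"endpoint_type must be one of {ENDPOINT_TYPES}")
        if self.endpoint_source not in ("human", "animal"):
            raise ValueError("endpoint_source must be 'human' or 'animal'")
        if self.secondary_value is not None and self.secondary_value >= self.value:
            raise ValueError("ADI/MRL must be below the primary threshold")


@dataclass(frozen=True)
class MOEResult:
    agent: str
    moe: np.ndarray  # per-iteration, +inf where exposure == 0
    percentiles: dict  # p1..p99 plus min/max
    moe_at_mean_exposure: Optional[float]  # None if all exposures are zero
    risk_band: str
    endpoint_source: str


def moe_distribution(exposures, threshold: ToxThreshold) -> MOEResult:
    """Per-iteration MOE vector and its summary against one threshold."""
    exposures = np.asarray(exposures, dtype=float)
    if np.any(exposures < 0):
        raise ValueError("exposures must be non-negative")
    with np.errstate(divide="ignore"):
        moe = np.where(exposures > 0, threshold.value / exposures, np.inf)
    pct = {
        f"p{p}": float(np.quantile(moe, p / 100.0, method="inverted_cdf"))
        for p in MOE_PERCENTILES
    }
    pct["min"] = float(np.min(moe))
    pct["max"] = float(np.max(moe))
    mean_exp = float(np.mean(exposures))
    at_mean = threshold.value / mean_exp if mean_exp > 0 else None
    band = categorize(pct["p50"], threshold.endpoint_source)
    return MOEResult(
        agent=threshold.agent,
        moe=moe,
        percentiles=pct,
        moe_at_mean_exposure=at_mean,
        risk_band=band,
        endpoint_source=threshold.endpoint_source,
    )


def categorize(median_moe: float, endpoint_source: str) -> str:
    """Risk band for a median MOE given the endpoint's species source."""
    if endpoint_source == "animal":
        lo, hi = 10.0, 100.0
    elif endpoint_source == "human":
        lo, hi = 1.0, 10.0
    else:
        raise ValueError("endpoint_source must be 'human' or 'animal'")
    if median_moe < lo:
        return "high risk"
    if median_moe < hi:
        return "risk"
    return "acceptable"
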