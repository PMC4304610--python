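"""Study-shaped synthetic data: concentration tables, calibration points,
spectrum traces.

The survey being emulated measured 54 e-liquid samples for seven agents.
Each agent is characterised by an incidence (fraction of samples with a
detectable concentration) and a concentration distribution for the positive
samples; non-detects are stored as 0 with a detect flag.  Label metadata
reproduces the labelling discordances observed in the market survey: some
products declared nicotine-free contain nicotine, and occasionally a
declared nicotine content is absent.

Two of the sparsely-detected agents have unpublished raw data;
:func:`reconstruct_sparse_vector` builds synthetic stand-in vectors that
match the printed incidence, overall mean/SD and concentration range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample

__all__ = [
    "AgentGenerator",
    "generate_sample_table",
    "generate_label_metadata",
    "generate_calibration_fixture",
    "generate_spectrum_trace",
    "reconstruct_sparse_vector",
    "audit_labels",
]


@dataclass(frozen=True)
class AgentGenerator:
    """Incidence plus positive-concentration distribution for one agent."""

    incidence: float
    spec: DistributionSpec
    unit: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("incidence must lie in [0, 1]")


def generate_sample_table(
    n_samples: int,
    generators: Dict[str, AgentGenerator],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a (sample x agent) concentration table in long format.

    Each cell is 0 with probability 1 - incidence, otherwise a draw from
    the agent's spec (truncated at 0 if not already).  Columns:
    sample_id, analyte, value, unit, detected.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for analyte, gen in generators.items():
        detected = rng.uniform(size=n_samples) < gen.incidence
        spec = gen.spec
        if spec.truncation is None and spec.family != "empirical_resample":
            spec = spec.truncated(lower=0.0)
        values = np.where(detected, sample(spec, n_samples, rng, "srs"), 0.0)
        values = np.maximum(values, 0.0)
        for i in range(n_samples):
            rows.append(
                {
                    "sample_id": f"S{i + 1:03d}",
                    "analyte": analyte,
                    "value": float(values[i]),
                    "unit": gen.unit,
                    "detected": bool(detected[i] and values[i] > 0),
                }
            )
    return pd.DataFrame(rows)


def generate_label_metadata(
    table: pd.DataFrame,
    n_false_free: int = 5,
    n_false_containing: int = 1,
    label_jitter_cv: float = 0.15,
    seed: int = 0,
    analyte: str = "nicotine",
) -> pd.DataFrame:
    """Attach declared-label metadata with controlled discordance.

    ``n_false_free`` nicotine-positive samples are labelled
    "nicotine-free", and ``n_false_containing`` nicotine-free samples get a
    fabricated declared content.  Concordant positives carry a declared
    value jittered around the measured one.  Adds columns declared_label
    ("nicotine-free", a numeric string, or "") per sample for ``analyte``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = table.copy()
    mask = out["analyte"] == analyte
    sub = out.loc[mask]
    pos_idx = sub.index[sub["detected"]].to_numpy()
    neg_idx = sub.index[~sub["detected"]].to_numpy()
    if len(pos_idx) < n_false_free or len(neg_idx) < n_false_containing:
        raise ValueError("not enough samples to apply the requested discordance")
    false_free = rng.choice(pos_idx, size=n_false_free, replace=False)
    false_cont = rng.choice(neg_idx, size=n_false_containing, replace=False)
    labels = pd.Series("", index=out.index, dtype=object)
    for i in pos_idx:
        measured = out.at[i, "value"]
        declared = measured * (1.0 + label_jitter_cv * rng.standard_normal())
        labels.at[i] = f"{max(declared, 0.1):.1f}"
    labels.loc[false_free] = "nicotine-free"
    labels.loc[neg_idx] = "nicotine-free"
    for i in false_cont:
        labels.at[i] = f"{rng.uniform(6, 54):.1f}"
    out["declared_label"] = ""
    out.loc[mask, "declared_label"] = labels.loc[mask]
    return out


def audit_labels(table: pd.DataFrame, analyte: str = "nicotine") -> dict:
    """Count labelling discordances in a labelled table."""
    sub = table[table["analyte"] == analyte]
    declared_free = sub["declared_label"] == f"{analyte}-free"
    false_free = int((declared_free & sub["detected"]).sum())
    declared_containing = ~declared_free & (sub["declared_label"] != "")
    false_containing = int((declared_containing & ~sub["detected"]).sum())
    return {
        "declared_free": int(declared_free.sum()),
        "false_free": false_free,
        "confirmed_free": int(declared_free.sum()) - false_free,
        "false_containing": false_containing,
    }


def generate_calibration_fixture(
    slope: float,
    intercept: float,
    noise_sd: float,
    levels: Sequence[float],
    replicates: int = 1,
    seed: int = 0,
) -> list:
    """(concentration, integral_ratio) points on a noisy line."""
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    rng = np.random.default_rng(seed)
    pts = []
    for c in levels:
        for _ in range(replicates):
            pts.append(
                (float(c), slope * c + intercept + noise_sd * rng.standard_normal())
            )
    return pts


def generate_spectrum_trace(
    peak_center: float,
    amplitude: float,
    width: float,
    noise_sd: float,
    n_points: int = 4096,
    x_range: Tuple[float, float] = (0.0, 10.0),
    seed: int = 0,
) -> np.ndarray:
    """Lorentzian peak plus white Gaussian noise on a uniform abscissa."""
    if width <= 0:
        raise ValueError("width must be positive")
    if n_points < 16:
        raise ValueError("need at least 16 points")
    rng = np.random.default_rng(seed)
    x = np.linspace(x_range[0], x_range[1], n_points)
    lorentz = amplitude * width**2 / ((x - peak_center) ** 2 + width**2)
    return lorentz + noise_sd * rng.standard_normal(n_points)


def reconstruct_sparse_vector(
    n: int,
    n_positive: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    max_iter: int = 200,
) -> np.ndarray:
    """Deterministic stand-in data vector for a sparsely detected agent.

    Builds ``n - n_positive`` zeros plus ``n_positive`` values inside
    ``[lo, hi]`` whose overall sample mean and SD (ddof=1) match the
    printed summary statistics as closely as the bounds allow.  Used for
    agents whose raw measurements were never published; the result is
    synthetic and only moment-matched, not the original data.

    Alternating projection: affine-correct the positive block to the exact
    target moments, then clip to the bounds, until converged.
    """
    if n_positive < 1 or n_positive > n:
        raise ValueError("need 1 <= n_positive <= n")
    target_sum = n * mean
    target_sumsq = (n - 1) * sd**2 + n * mean**2
    pos_mean = target_sum / n_positive
    pos_sumsq = target_sumsq / n_positive
    pos_var = max(pos_sumsq - pos_mean**2, 0.0)
    x = np.linspace(lo, hi, n_positive)
    for _ in range(max_iter):
        m, s = np.mean(x), np.std(x)
        x = pos_mean + (x - m) * (np.sqrt(pos_var) / s if s > 0 else 0.0)
        x_clipped = np.clip(x, lo, hi)
        if np.allclose(x, x_clipped, atol=1e-12):
            break
        x = x_clipped
    full = np.concatenate([np.zeros(n - n_positive), np.sort(np.clip(x, lo, hi))])
    return full
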