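"""Method-validation statistics for internal-reference NMR quantitation.

Quantitative NMR against an internal intensity reference (TSP in water,
TMS in CDCl3) reduces each analyte to a calibration line of integral ratio
versus concentration.  This module provides the validation arithmetic:

* calibration fit (OLS slope/intercept, residual SD, Pearson R);
* detection and quantification limits, either from the residual standard
  deviation of a low-range calibration line (LOD = 3.3 s_yx / slope,
  LOQ = 10 s_yx / slope) or from the signal-to-noise ratio of a spectral
  peak (SNR 3 and 10 conventions);
* recovery and precision from standard-addition experiments;
* paired comparison of two quantification methods (Pearson r, OLS slope
  and intercept with 95% confidence intervals, and the verdict that no
  proportional / systematic difference exists when the slope CI covers 1
  and the intercept CI covers 0).

Tube-to-sample conversion helpers encode the two sample preparations:
aqueous (60 uL sample in 600 uL, dilution 10) and chloroform (100 uL in
900 uL, dilution 9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "MethodComparison",
    "fit_calibration",
    "lod_loq_from_regression",
    "lod_loq_from_snr",
    "recovery_and_precision",
    "method_comparison",
    "tube_to_sample",
    "DILUTION_AQUEOUS",
    "DILUTION_CHLOROFORM",
]

DILUTION_AQUEOUS = 600.0 / 60.0  # 10x
DILUTION_CHLOROFORM = 900.0 / 100.0  # 9x

K_LOD_DEFAULT = 3.3
K_LOQ_DEFAULT = 10.0
#: Noise amplitude in the SNR denominator is 2 x the noise-window SD
#: (peak-to-peak style convention of the Bruker sino routine).
SNR_NOISE_MULTIPLIER = 2.0


@dataclass(frozen=True)
class CalibrationModel:
    """An intensity-ratio-versus-concentration calibration line."""

    slope: float
    intercept: float
    residual_sd: float  # s_y/x with n-2 denominator
    correlation: float  # Pearson R
    n_points: int
    conc_range: Tuple[float, float]


@dataclass(frozen=True)
class MethodComparison:
    n_pairs: int
    pearson_r: float
    p_value: float
    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    intercept_ci: Tuple[float, float]
    slope_ci_contains_1: bool
    intercept_ci_contains_0: bool

    @property
    def methods_agree(self) -> bool:
        """No proportional and no systematic difference detected."""
        return self.slope_ci_contains_1 and self.intercept_ci_contains_0


def fit_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationModel:
    """OLS calibration fit from (concentration, integral_ratio) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 calibration points")
    conc, ratio = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    fit = stats.linregress(conc, ratio)
    resid = ratio - (fit.intercept + fit.slope * conc)
    n = conc.size
    s_yx = math.sqrt(float(np.sum(resid**2)) / (n - 2)) if n > 2 else 0.0
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=s_yx,
        correlation=float(fit.rvalue),
        n_points=n,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def lod_loq_from_regression(
    cal: CalibrationModel,
    k_lod: float = K_LOD_DEFAULT,
    k_loq: float = K_LOQ_DEFAULT,
) -> Tuple[float, float]:
    """Detection limits from the residual SD of the calibration line.

    LOD = k_lod * s_yx / slope and LOQ = k_loq * s_yx / slope, in the
    concentration unit of the calibration.  Equivalently the LOD is the
    smallest concentration whose predicted signal exceeds the intercept by
    k_lod residual SDs.
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return (
        k_lod * cal.residual_sd / cal.slope,
        k_loq * cal.residual_sd / cal.slope,
    )


def lod_loq_from_snr(
    trace: Sequence[float],
    signal_window: Tuple[int, int],
    noise_window: Tuple[int, int],
    concentration: float,
) -> dict:
    """Detection limits from a peak's signal-to-noise ratio.

    SNR = (peak amplitude in the signal window) / (2 * SD of the noise
    window); LOD and LOQ are the concentrations at which the SNR would be
    3 and 10.  A zero noise SD is flagged and both limits reported as 0.
    """
    x = np.asarray(trace, dtype=float)
    s0, s1 = signal_window
    n0, n1 = noise_window
    if s1 <= s0 or n1 <= n0:
        raise ValueError("windows must be non-empty")
    if max(s0, n0) < min(s1, n1):
        raise ValueError("signal and noise windows must be disjoint")
    peak = float(np.max(x[s0:s1]))
    noise_sd = float(np.std(x[n0:n1]))
    if noise_sd == 0.0:
        return {"snr": math.inf, "lod": 0.0, "loq": 0.0, "flag": "zero-noise"}
    snr = peak / (SNR_NOISE_MULTIPLIER * noise_sd)
    if snr <= 0:
        return {"snr": snr, "lod": math.inf, "loq": math.inf, "flag": "no-signal"}
    return {
        "snr": snr,
        "lod": 3.0 * concentration / snr,
        "loq": 10.0 * concentration / snr,
        "flag": "",
    }


def recovery_and_precision(
    measured: Sequence[float],
    spiked: Sequence[float],
    baseline: float = 0.0,
    replicates: Optional[Sequence[float]] = None,
) -> dict:
    """Standard-addition recovery and replicate precision.

    Per spiking level: recovery_i = 100 * (measured_i - baseline) / spiked_i.
    The CV (in %) is computed from ``replicates`` — repeated measurements of
    one sample — when given.
    """
    measured = np.asarray(measured, dtype=float)
    spiked = np.asarray(spiked, dtype=float)
    if measured.shape != spiked.shape:
        raise ValueError("measured and spiked must align")
    if np.any(spiked <= 0):
        raise ValueError("spiked amounts must be positive")
    rec = 100.0 * (measured - baseline) / spiked
    out = {
        "recovery_per_level": rec.tolist(),
        "mean_recovery": float(np.mean(rec)),
    }
    if replicates is not None:
        r = np.asarray(replicates, dtype=float)
        m = float(np.mean(r))
        out["cv"] = 100.0 * float(np.std(r, ddof=1)) / m if m != 0 else math.inf
    return out


def method_comparison(
    pairs: Sequence[Tuple[Optional[float], Optional[float]]],
    nd_policy: str = "as_zero",
) -> MethodComparison:
    """Compare two quantification methods on paired results.

    ``pairs`` holds (method A, method B) values with ``None`` marking a
    non-detect.  ``nd_policy="as_zero"`` replaces non-detects by 0 (pairs
    where both methods report n.d. then anchor the regression at the
    origin); ``"drop"`` removes any pair containing a non-detect.  Returns
    Pearson r and the OLS line of B on A with 95% CIs on slope and
    intercept.
    """
    a_vals, b_vals = [], []
    for a, b in pairs:
        if nd_policy == "as_zero":
            a_vals.append(0.0 if a is None else float(a))
            b_vals.append(0.0 if b is None else float(b))
        elif nd_policy == "drop":
            if a is None or b is None:
                continue
            a_vals.append(float(a))
            b_vals.append(float(b))
        else:
            raise ValueError("nd_policy must be 'as_zero' or 'drop'")
    a_arr, b_arr = np.asarray(a_vals), np.asarray(b_vals)
    if a_arr.size < 3:
        raise ValueError("need at least 3 usable pairs")
    fit = stats.linregress(a_arr, b_arr)
    t_crit = stats.t.ppf(0.975, a_arr.size - 2)
    slope_ci = (fit.slope - t_crit * fit.stderr, fit.slope + t_crit * fit.stderr)
    icpt_ci = (
        fit.intercept - t_crit * fit.intercept_stderr,
        fit.intercept + t_crit * fit.intercept_stderr,
    )
    return MethodComparison(
        n_pairs=int(a_arr.size),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept=float(fit.intercept),
        intercept_ci=(float(icpt_ci[0]), float(icpt_ci[1])),
        slope_ci_contains_1=bool(slope_ci[0] <= 1.0 <= slope_ci[1]),
        intercept_ci_contains_0=bool(icpt_ci[0] <= 0.0 <= icpt_ci[1]),
    )


def tube_to_sample(conc_mg_per_l: float, dilution: float = DILUTION_AQUEOUS) -> float:
    """Convert an in-tube concentration (mg/L) to mg/ml of original sample."""
    return conc_mg_per_l * dilution / 1000.0
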