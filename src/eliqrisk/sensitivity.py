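"""Input-influence ranking via standardized multiple regression.

The simulated exposure is regressed on the four simulated inputs after
z-scoring both sides; the resulting slopes (standardized regression
coefficients) rank the inputs by |coefficient|.  The exposure formula is
multiplicative, so the linear fit is an approximation — its R² is reported
so the quality of the linearization is visible.  A rank-transformed variant
(Spearman-style) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["SensitivityReport", "standardized_regression"]

DEFAULT_INPUT_NAMES = ("concentration", "amount", "vaporization", "bodyweight")


@dataclass(frozen=True)
class SensitivityReport:
    coefficients: dict  # input name -> standardized slope
    ranking: Tuple[str, ...]  # by decreasing |coefficient|
    r_squared: float
    zero_variance: Tuple[str, ...]  # inputs flagged with coefficient 0
    rank_based: bool = False


def standardized_regression(
    inputs: np.ndarray,
    output: Sequence[float],
    input_names: Sequence[str] = DEFAULT_INPUT_NAMES,
    rank_based: bool = False,
) -> SensitivityReport:
    """OLS of the z-scored output on the z-scored inputs.

    ``inputs`` is an (n, k) matrix of per-iteration input draws and
    ``output`` the matching exposure vector, n > 10.  Zero-variance columns
    are excluded from the fit and reported with coefficient 0 and a flag.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(output, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("inputs must be (n, k) with n matching output")
    n, k = X.shape
    if n <= 10:
        raise ValueError("need more than 10 iterations")
    if len(input_names) != k:
        raise ValueError("one name per input column required")
    if rank_based:
        X = np.apply_along_axis(stats.rankdata, 0, X)
        y = stats.rankdata(y)
    sd_x = np.std(X, axis=0)
    sd_y = float(np.std(y))
    live = sd_x > 0
    if sd_y == 0 or not live.any():
        raise ValueError("output and at least one input need nonzero variance")
    Z = (X[:, live] - X[:, live].mean(axis=0)) / sd_x[live]
    zy = (y - y.mean()) / sd_y
    design = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(design, zy, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((zy - fitted) ** 2))
    ss_tot = float(np.sum(zy**2))
    coefs = dict.fromkeys(input_names, 0.0)
    for name, b in zip(np.asarray(input_names)[live], beta[1:]):
        coefs[str(name)] = float(b)
    ranking = tuple(sorted(coefs, key=lambda nm: abs(coefs[nm]), reverse=True))
    return SensitivityReport(
        coefficients=coefs,
        ranking=ranking,
        r_squared=1.0 - ss_res / ss_tot,
        zero_variance=tuple(str(nm) for nm, ok in zip(input_names, live) if not ok),
        rank_based=rank_based,
    )
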