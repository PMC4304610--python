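"""Risk-function distributions in the @Risk parameter dialect.

Every uncertain model input (a "risk function") is a univariate distribution
that may carry an additive shift and a one- or two-sided truncation.  Seven
families are supported:

``normal``
    ``params = (mu, sigma)``.
``normal_from_quantiles``
    ``params = (p_lo, q_lo, p_hi, q_hi)`` — a normal specified by two
    quantiles (the @Risk *NormalAlt* form); resolved to ``(mu, sigma)`` on
    construction.
``weibull_shifted``
    ``params = (shape, scale)`` plus ``shift``; the @Risk convention
    ``RiskWeibull(shape; scale; RiskShift(d))`` meaning ``X = W + d``.
``triangular``
    ``params = (minimum, mode, maximum)``.
``loglogistic``
    ``params = (location, scale, shape)`` — the three-parameter @Risk
    convention with CDF ``F(x) = 1 / (1 + ((x - loc)/scale)**(-shape))``
    for ``x > loc`` (scipy's ``fisk`` with ``loc``/``scale``/``c``).
``uniform``
    ``params = (lower, upper)``.
``empirical_resample``
    ``params`` is the full data vector (zeros for non-detects included);
    sampling draws with replacement, uniform weights.

Shift applies before truncation: truncation bounds are expressed on the
shifted variable.  Truncation is implemented exactly by restricting the
inverse CDF to ``[F(lo), F(hi)]`` — no rejection loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "SpecValidationError",
    "quantile",
    "cdf",
    "analytic_mean",
    "numeric_mean",
    "mean",
    "normal_from_quantiles",
    "sample",
    "FAMILIES",
]

FAMILIES = (
    "normal",
    "normal_from_quantiles",
    "weibull_shifted",
    "triangular",
    "loglogistic",
    "uniform",
    "empirical_resample",
)


class SpecValidationError(ValueError):
    """Raised when a distribution spec violates its family's constraints."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric or empirical risk function with optional shift/truncation.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Family-specific parameter tuple (see module docstring); for
        ``empirical_resample`` the full data vector.
    shift
        Additive offset applied to the base variate (default 0).
    truncation
        Optional ``(lower, upper)`` bounds on the *shifted* variable; either
        side may be ``None`` (open).
    unit
        Concentration or factor unit string, carried for bookkeeping.
    """

    family: str
    params: Tuple[float, ...]
    shift: float = 0.0
    truncation: Optional[Tuple[Optional[float], Optional[float]]] = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecValidationError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "shift", float(self.shift))
        p = self.params
        if self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise SpecValidationError("normal requires (mu, sigma) with sigma > 0")
        elif self.family == "normal_from_quantiles":
            if len(p) != 4:
                raise SpecValidationError(
                    "normal_from_quantiles requires (p_lo, q_lo, p_hi, q_hi)"
                )
            mu, sigma = normal_from_quantiles(p[0], p[1], p[2], p[3])
            object.__setattr__(self, "family", "normal")
            object.__setattr__(self, "params", (mu, sigma))
        elif self.family == "weibull_shifted":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise SpecValidationError(
                    "weibull_shifted requires shape > 0 and scale > 0"
                )
        elif self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]) or p[0] == p[2]:
                raise SpecValidationError("triangular requires min <= mode <= max")
        elif self.family == "loglogistic":
            if len(p) != 3 or p[1] <= 0 or p[2] <= 0:
                raise SpecValidationError(
                    "loglogistic requires scale > 0 and shape > 0"
                )
        elif self.family == "uniform":
            if len(p) != 2 or p[0] >= p[1]:
                raise SpecValidationError("uniform requires lower < upper")
        elif self.family == "empirical_resample":
            if len(p) == 0:
                raise SpecValidationError("empirical_resample requires data")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and not lo < hi:
                raise SpecValidationError("truncation requires lower < upper")
            plo, phi = self._trunc_probs()
            if not phi > plo:
                raise SpecValidationError("truncated support has zero probability mass")

    # -- base (shifted, untruncated) distribution -------------------------

    def _frozen(self):
        """scipy frozen distribution of the shifted base variable."""
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p[0] + self.shift, scale=p[1])
        if self.family == "weibull_shifted":
            return stats.weibull_min(p[0], loc=self.shift, scale=p[1])
        if self.family == "triangular":
            a, m, b = p
            return stats.triang((m - a) / (b - a), loc=a + self.shift, scale=b - a)
        if self.family == "loglogistic":
            loc, scale, shape = p
            return stats.fisk(shape, loc=loc + self.shift, scale=scale)
        if self.family == "uniform":
            return stats.uniform(loc=p[0] + self.shift, scale=p[1] - p[0])
        raise SpecValidationError(f"no scipy frozen form for {self.family}")

    def _base_cdf(self, x: np.ndarray) -> np.ndarray:
        if self.family == "empirical_resample":
            data = np.asarray(self.params) + self.shift
            return np.searchsorted(np.sort(data), x, side="right") / data.size
        return self._frozen().cdf(x)

    def _base_quantile(self, u: np.ndarray) -> np.ndarray:
        if self.family == "empirical_resample":
            data = np.sort(np.asarray(self.params) + self.shift)
            # inverse ECDF (type 1): smallest x with F(x) >= u
            idx = np.minimum(np.ceil(np.asarray(u) * data.size).astype(int) - 1, data.size - 1)
            return data[np.maximum(idx, 0)]
        return self._frozen().ppf(u)

    def _trunc_probs(self) -> Tuple[float, float]:
        """Base CDF mass at the truncation bounds, (F(lo), F(hi))."""
        lo, hi = (None, None) if self.truncation is None else self.truncation
        plo = 0.0 if lo is None else float(self._base_cdf(np.asarray(lo)))
        phi = 1.0 if hi is None else float(self._base_cdf(np.asarray(hi)))
        return plo, phi

    # -- convenience ------------------------------------------------------

    def truncated(self, lower=None, upper=None) -> "DistributionSpec":
        return replace(self, truncation=(lower, upper))

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if self.shift:
            d["shift"] = self.shift
        if self.truncation is not None:
            d["truncate"] = [self.truncation[0], self.truncation[1]]
        if self.unit:
            d["unit"] = self.unit
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        trunc = d.get("truncate")
        return cls(
            family=d["family"],
            params=tuple(d["params"]),
            shift=float(d.get("shift", 0.0)),
            truncation=None if trunc is None else (trunc[0], trunc[1]),
            unit=d.get("unit", ""),
        )


# -- operations -----------------------------------------------------------


def quantile(spec: DistributionSpec, u) -> np.ndarray | float:
    """Inverse CDF of the shifted, truncated distribution.

    ``u`` must lie strictly in (0, 1); monotone non-decreasing in ``u`` and
    always inside the truncation bounds.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    plo, phi = spec._trunc_probs()
    out = spec._base_quantile(plo + u_arr * (phi - plo))
    if spec.truncation is not None:
        lo, hi = spec.truncation
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        out = np.clip(out, lo, hi)
    return out if np.ndim(u) else float(out)


def cdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """CDF of the shifted, truncated distribution."""
    x_arr = np.asarray(x, dtype=float)
    plo, phi = spec._trunc_probs()
    out = np.clip((spec._base_cdf(x_arr) - plo) / (phi - plo), 0.0, 1.0)
    if spec.truncation is not None:
        lo, hi = spec.truncation
        if lo is not None:
            out = np.where(x_arr < lo, 0.0, out)
        if hi is not None:
            out = np.where(x_arr >= hi, 1.0, out)
    return out if np.ndim(x) else float(out)


def normal_from_quantiles(p_lo: float, q_lo: float, p_hi: float, q_hi: float):
    """Solve for the unique (mu, sigma) with the two stated quantiles.

    ``Normal(mu, sigma)`` has its ``p_lo`` quantile at ``q_lo`` and its
    ``p_hi`` quantile at ``q_hi``.
    """
    if not (0.0 < p_lo < p_hi < 1.0):
        raise SpecValidationError("need 0 < p_lo < p_hi < 1")
    if not q_lo < q_hi:
        raise SpecValidationError("need q_lo < q_hi")
    z_lo, z_hi = stats.norm.ppf([p_lo, p_hi])
    sigma = (q_hi - q_lo) / (z_hi - z_lo)
    mu = q_lo - sigma * z_lo
    return float(mu), float(sigma)


def analytic_mean(spec: DistributionSpec) -> Optional[float]:
    """Closed-form mean of the shifted, truncated distribution.

    Returns ``None`` ("unavailable") where no closed form exists — callers
    should fall back to :func:`numeric_mean`.  Available for: normal
    (optionally truncated), uniform (truncation intersects the support),
    untruncated triangular / Weibull / log-logistic (shape > 1), and
    empirical data (truncation restricts the data window).
    """
    p = spec.params
    lo, hi = (None, None) if spec.truncation is None else spec.truncation
    if spec.family == "empirical_resample":
        data = np.asarray(p) + spec.shift
        keep = np.ones(data.size, dtype=bool)
        if lo is not None:
            keep &= data >= lo
        if hi is not None:
            keep &= data <= hi
        return float(np.mean(data[keep]))
    if spec.family == "normal":
        mu, sd = p[0] + spec.shift, p[1]
        a = -np.inf if lo is None else (lo - mu) / sd
        b = np.inf if hi is None else (hi - mu) / sd
        return float(stats.truncnorm(a, b, loc=mu, scale=sd).mean())
    if spec.family == "uniform":
        a, b = p[0] + spec.shift, p[1] + spec.shift
        if lo is not None:
            a = max(a, lo)
        if hi is not None:
            b = min(b, hi)
        return (a + b) / 2.0
    if lo is not None or hi is not None:
        return None
    if spec.family == "triangular":
        return (p[0] + p[1] + p[2]) / 3.0 + spec.shift
    if spec.family == "weibull_shifted":
        shape, scale = p
        return scale * math.gamma(1.0 + 1.0 / shape) + spec.shift
    if spec.family == "loglogistic":
        loc, scale, shape = p
        if shape <= 1.0:
            return None  # mean divergent
        c = math.pi / shape
        return loc + spec.shift + scale * c / math.sin(c)
    return None


def numeric_mean(spec: DistributionSpec, n_nodes: int = 4096) -> float:
    """Mean by Gauss–Legendre quadrature of the quantile function on (0,1).

    Robust across all families including truncated heavy-tailed ones, since
    the quantile of a truncated distribution is bounded whenever the bounds
    are finite; for open tails the quadrature nodes stay inside (0, 1).
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (nodes + 1.0)
    return float(np.sum(0.5 * weights * quantile(spec, u)))


def mean(spec: DistributionSpec) -> float:
    """Closed-form mean where available, numeric quadrature otherwise."""
    m = analytic_mean(spec)
    return numeric_mean(spec) if m is None else m


def sample(
    spec: DistributionSpec,
    n: int,
    rng_seed,
    method: str = "lhs",
) -> np.ndarray:
    """Draw ``n`` values by inverse-CDF sampling.

    ``method="srs"`` inverts n iid uniforms; ``method="lhs"`` places exactly
    one uniform in each equal-probability stratum ``[(i-1)/n, i/n)`` and
    randomly permutes the stratum order (Latin Hypercube sampling for a
    single input).  ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if method == "srs":
        u = rng.uniform(size=n)
    elif method == "lhs":
        u = (rng.permutation(n) + rng.uniform(size=n)) / n
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    # keep u strictly inside (0,1) for the open-interval quantile contract
    eps = np.finfo(float).tiny
    return np.asarray(quantile(spec, np.clip(u, eps, 1.0 - eps)))
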