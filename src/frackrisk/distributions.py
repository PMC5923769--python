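"""Parametric concentration/volume distributions anchored at two quantiles.

The study's raw inputs are summarised as a distribution family plus a
(median, 95th-percentile) pair per variable.  This module turns those
anchors into fully specified scipy distributions, fits families to raw
samples by maximum likelihood, and draws reproducible samples.

Families
--------
``lognormal``        scipy ``lognorm`` with loc fixed at 0
``triangular``       scipy ``triang`` with the lower bound fixed at 0
``logistic``         scipy ``logistic``
``minimum_extreme``  Gumbel minimum (left-skewed extreme value), scipy ``gumbel_l``
``pareto``           scipy ``pareto`` with loc 0 (scale = minimum support point)
``weibull``          scipy ``weibull_min`` with loc 0

For the two-parameter families the (median, p95) pair determines the
parameters in closed form.  The triangular family has three parameters;
the lower bound is pinned at 0 (concentrations are non-negative) and the
mode and maximum are solved from the two anchors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "FAMILIES",
    "InfeasibleAnchorsError",
    "from_quantiles",
    "sample",
    "fit_mle",
]

log = logging.getLogger(__name__)

FAMILIES = (
    "lognormal",
    "triangular",
    "logistic",
    "minimum_extreme",
    "pareto",
    "weibull",
)

_Z = {}  # cached standard quantile constants
_LN2 = math.log(2.0)
_LN20 = math.log(20.0)


class InfeasibleAnchorsError(ValueError):
    """Raised when a (median, p95) pair cannot be realised by a proper CDF."""


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric family with concrete parameters.

    ``params`` uses scipy's shape/loc/scale conventions for the family's
    underlying ``scipy.stats`` distribution.  ``anchors`` records the
    (median, p95) pair the spec was constructed from, when applicable.
    """

    family: str
    params: Mapping[str, float]
    anchors: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    # -- scipy bridge ---------------------------------------------------

    def frozen(self):
        """Return the frozen scipy distribution for this spec."""
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "triangular":
            b = p["maximum"]
            return stats.triang(c=p["mode"] / b, loc=0.0, scale=b)
        if self.family == "logistic":
            return stats.logistic(loc=p["loc"], scale=p["scale"])
        if self.family == "minimum_extreme":
            return stats.gumbel_l(loc=p["loc"], scale=p["scale"])
        if self.family == "pareto":
            return stats.pareto(b=p["shape"], scale=p["scale"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        raise AssertionError(self.family)

    def cdf(self, x):
        return self.frozen().cdf(x)

    def quantile(self, q):
        return self.frozen().ppf(q)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    @property
    def p95(self) -> float:
        return float(self.quantile(0.95))

    def mean(self) -> float:
        return float(self.frozen().mean())

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": dict(self.params)}
        if self.anchors is not None:
            d["anchors"] = list(self.anchors)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        anchors = tuple(d["anchors"]) if d.get("anchors") else None
        return cls(family=d["family"], params=dict(d["params"]), anchors=anchors)


def _require_ordered(family: str, median: float, p95: float) -> None:
    if median <= 0:
        raise ValueError(f"{family}: median must be positive, got {median}")
    if p95 <= median:
        raise InfeasibleAnchorsError(
            f"{family}: p95 ({p95}) must exceed the median ({median}); "
            "no proper CDF can place the 95th percentile at or below the median"
        )


def from_quantiles(
    family: str,
    median: float,
    p95: float,
    *,
    swap_if_infeasible: bool = False,
) -> DistributionSpec:
    """Construct a spec whose CDF passes through (median, 0.5) and (p95, 0.95).

    Parameters
    ----------
    family : one of :data:`FAMILIES`
    median, p95 : positive quantile anchors, p95 > median
    swap_if_infeasible : if True and p95 < median, swap the anchors and log a
        data-quality warning instead of raising (used for the beryllium row,
        whose printed anchors are out of order).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if swap_if_infeasible and 0 < p95 < median:
        log.warning(
            "anchors out of order for %s (median=%g > p95=%g); swapping", family, median, p95
        )
        median, p95 = p95, median
    _require_ordered(family, median, p95)

    if family == "lognormal":
        z95 = stats.norm.ppf(0.95)
        mu = math.log(median)
        sigma = (math.log(p95) - mu) / z95
        params = {"mu": mu, "sigma": sigma}
    elif family == "logistic":
        # quantile: loc + scale * ln(q/(1-q)); ln(0.95/0.05) = ln 19
        params = {"loc": median, "scale": (p95 - median) / math.log(19.0)}
    elif family == "minimum_extreme":
        # Gumbel-min quantile: loc + scale * ln(-ln(1-q))
        a50 = math.log(-math.log(0.5))   # = ln(ln 2) < 0
        a95 = math.log(-math.log(0.05))  # = ln(ln 20)
        scale = (p95 - median) / (a95 - a50)
        params = {"loc": median - scale * a50, "scale": scale}
    elif family == "pareto":
        # survival (scale/x)^shape: shape = ln 10 / ln(p95/median)
        shape = math.log(10.0) / math.log(p95 / median)
        scale = median * 0.5 ** (1.0 / shape)
        params = {"shape": shape, "scale": scale}
    elif family == "weibull":
        shape = math.log(_LN20 / _LN2) / math.log(p95 / median)
        scale = median / _LN2 ** (1.0 / shape)
        params = {"shape": shape, "scale": scale}
    elif family == "triangular":
        params = _triangular_from_quantiles(median, p95)
    else:  # pragma: no cover
        raise AssertionError(family)

    spec = DistributionSpec(family=family, params=params, anchors=(median, p95))
    # construction guarantee: both anchors reproduced
    for q, x in ((0.5, median), (0.95, p95)):
        if not math.isclose(spec.cdf(x), q, abs_tol=1e-9):  # pragma: no cover
            raise AssertionError(f"anchor check failed for {family}: CDF({x})={spec.cdf(x)}")
    return spec


def _tri_unit_quantile(p: float, u: float) -> float:
    """Quantile of triangular(0, u, 1) at probability p."""
    if p <= u:
        return math.sqrt(p * u)
    return 1.0 - math.sqrt((1.0 - p) * (1.0 - u))


#: Attainable p95/median ratios for a zero-based triangular distribution:
#: the ratio is largest for mode 0 and smallest for mode = maximum.
_TRI_RATIO_MAX = (1.0 - math.sqrt(0.05)) / (1.0 - math.sqrt(0.5))  # ~2.6508
_TRI_RATIO_MIN = math.sqrt(0.95) / math.sqrt(0.5)  # ~1.3784


def _triangular_from_quantiles(median: float, p95: float) -> dict:
    """Solve mode and maximum of a triangular(0, mode, maximum) from two anchors.

    The quantile ratio q95/q50 of a unit triangular is strictly monotone in
    the relative mode u = mode/maximum, so u is found by a bracketed root
    solve and the scale follows from the median.
    """
    target = p95 / median
    if not (_TRI_RATIO_MIN < target < _TRI_RATIO_MAX):
        raise InfeasibleAnchorsError(
            f"triangular with lower bound 0 cannot place p95/median = {target:.4g}; "
            f"attainable ratios are ({_TRI_RATIO_MIN:.4f}, {_TRI_RATIO_MAX:.4f})"
        )

    def ratio_residual(u: float) -> float:
        return _tri_unit_quantile(0.95, u) / _tri_unit_quantile(0.5, u) - target

    u = optimize.brentq(ratio_residual, 1e-12, 1.0 - 1e-12, xtol=1e-15)
    b = median / _tri_unit_quantile(0.5, u)
    return {"mode": u * b, "maximum": b}


def sample(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator,
    *,
    nonnegative: bool = False,
    upper: float | None = None,
) -> np.ndarray:
    """Draw ``n`` values from ``spec``; identical (spec, n, seed) -> identical draws.

    ``nonnegative`` rejects negative draws (unbounded families used for
    concentrations); ``upper`` rejects draws above a ceiling (spill volumes).
    Rejection keeps the draw count exact while preserving the conditional law.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = spec.frozen()
    out = np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    bad = _out_of_bounds(out, nonnegative, upper)
    guard = 0
    while bad.any():
        out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
        bad = _out_of_bounds(out, nonnegative, upper)
        guard += 1
        if guard > 10_000:  # pragma: no cover
            raise RuntimeError("rejection sampling failed to converge")
    return out


def _out_of_bounds(x: np.ndarray, nonnegative: bool, upper: float | None) -> np.ndarray:
    bad = np.zeros(x.shape, dtype=bool)
    if nonnegative:
        bad |= x < 0
    if upper is not None:
        bad |= x > upper
    return bad


def fit_mle(family: str, data: Sequence[float]) -> tuple[DistributionSpec, float]:
    """Maximum-likelihood fit of ``family`` to raw samples.

    Returns the fitted spec and its log-likelihood.  Location parameters of
    non-negative families (lognormal, weibull, pareto, triangular) are pinned
    at 0, matching the anchor-construction convention.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(data, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all observations equal")

    if family in ("lognormal", "weibull", "pareto", "triangular"):
        if np.any(x <= 0):
            raise ValueError(f"{family} support is (0, inf); data contain non-positive values")

    if family == "lognormal":
        lx = np.log(x)
        mu, sigma = float(lx.mean()), float(lx.std(ddof=0))
        params = {"mu": mu, "sigma": sigma}
    elif family == "weibull":
        shape, _, scl = stats.weibull_min.fit(x, floc=0)
        params = {"shape": float(shape), "scale": float(scl)}
    elif family == "pareto":
        scl = float(x.min())
        shape = x.size / float(np.sum(np.log(x / scl)))
        params = {"shape": shape, "scale": scl}
    elif family == "logistic":
        loc, scl = stats.logistic.fit(x)
        params = {"loc": float(loc), "scale": float(scl)}
    elif family == "minimum_extreme":
        loc, scl = stats.gumbel_l.fit(x)
        params = {"loc": float(loc), "scale": float(scl)}
    elif family == "triangular":
        c, _, scl = stats.triang.fit(x, floc=0)
        params = {"mode": float(c * scl), "maximum": float(scl)}
    else:  # pragma: no cover
        raise AssertionError(family)

    spec = DistributionSpec(family=family, params=params)
    loglik = float(np.sum(spec.frozen().logpdf(x)))
    return spec, loglik
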