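"""Parametric input distributions and Anderson–Darling family selection.

Concentration inputs to the probabilistic risk model are described by a small
set of parametric families.  Campaign data are screened with the
Anderson–Darling statistic after per-family maximum-likelihood fitting; in
ambient halocarbon data the lognormal family usually wins, which is why it is
the default concentration model everywhere else in the package.

Selection is by minimal A² statistic rather than p-value: critical values for
composite hypotheses (estimated parameters) differ by family, while the raw
statistic ranks fits on a common footing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

FAMILIES = ("point", "uniform", "triangular", "normal", "lognormal")


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Solve (μ, σ) of ln X from the arithmetic mean and SD of X.

    σ² = ln(1 + (sd/mean)²),  μ = ln(mean) − σ²/2.
    """
    if not mean > 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model input.

    ``params`` are family-specific:

    - ``point``:      value
    - ``uniform``:    low, high
    - ``triangular``: low, mode, high
    - ``normal``:     mean, sd
    - ``lognormal``:  mu, sigma  (moments of ln X)

    Optional truncation bounds restrict the support; sampling and ppf use the
    conditional (renormalised) distribution.
    """

    family: str
    params: Mapping[str, float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValueError("uniform requires low < high")
        if self.family == "triangular" and not p["low"] <= p["mode"] <= p["high"]:
            raise ValueError("triangular requires low <= mode <= high")
        if self.family == "normal" and not p["sd"] >= 0:
            raise ValueError("normal requires sd >= 0")
        if self.family == "lognormal" and not p["sigma"] >= 0:
            raise ValueError("lognormal requires sigma >= 0")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError("truncation bounds must be ordered")

    # -- constructors -----------------------------------------------------
    @staticmethod
    def point(value: float) -> "DistributionSpec":
        return DistributionSpec("point", {"value": float(value)})

    @staticmethod
    def uniform(low: float, high: float) -> "DistributionSpec":
        return DistributionSpec("uniform", {"low": float(low), "high": float(high)})

    @staticmethod
    def triangular(low: float, mode: float, high: float) -> "DistributionSpec":
        return DistributionSpec(
            "triangular", {"low": float(low), "mode": float(mode), "high": float(high)}
        )

    @staticmethod
    def normal(mean: float, sd: float, lower: float = None, upper: float = None) -> "DistributionSpec":
        return DistributionSpec("normal", {"mean": float(mean), "sd": float(sd)}, lower, upper)

    @staticmethod
    def lognormal(mu: float, sigma: float) -> "DistributionSpec":
        return DistributionSpec("lognormal", {"mu": float(mu), "sigma": float(sigma)})

    @staticmethod
    def lognormal_from_moments(mean: float, sd: float) -> "DistributionSpec":
        mu, sigma = lognormal_params_from_moments(mean, sd)
        return DistributionSpec.lognormal(mu, sigma)

    # -- scipy plumbing ----------------------------------------------------
    def _frozen(self):
        p = self.params
        if self.family == "uniform":
            return stats.uniform(loc=p["low"], scale=p["high"] - p["low"])
        if self.family == "triangular":
            scale = p["high"] - p["low"]
            c = 0.5 if scale == 0 else (p["mode"] - p["low"]) / scale
            return stats.triang(c=c, loc=p["low"], scale=scale)
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        raise ValueError(f"family {self.family!r} has no continuous distribution")

    @property
    def is_degenerate(self) -> bool:
        if self.family == "point":
            return True
        if self.family == "normal" and self.params["sd"] == 0:
            return True
        if self.family == "lognormal" and self.params["sigma"] == 0:
            return True
        return False

    def _point_value(self) -> float:
        if self.family == "point":
            return self.params["value"]
        if self.family == "normal":
            return self.params["mean"]
        if self.family == "lognormal":
            return math.exp(self.params["mu"])
        raise ValueError("not a degenerate spec")

    def cdf(self, x):
        if self.is_degenerate:
            return (np.asarray(x, dtype=float) >= self._point_value()).astype(float)
        dist = self._frozen()
        lo = dist.cdf(self.lower) if self.lower is not None else 0.0
        hi = dist.cdf(self.upper) if self.upper is not None else 1.0
        return np.clip((dist.cdf(x) - lo) / (hi - lo), 0.0, 1.0)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.is_degenerate:
            out = np.full_like(q, self._point_value())
            return out.item() if out.ndim == 0 else out
        dist = self._frozen()
        lo = dist.cdf(self.lower) if self.lower is not None else 0.0
        hi = dist.cdf(self.upper) if self.upper is not None else 1.0
        return dist.ppf(lo + q * (hi - lo))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.is_degenerate:
            return np.full(n, self._point_value())
        # inverse-CDF sampling keeps truncation exact and the draw count
        # identical across specs, so replication streams stay aligned
        return np.asarray(self.ppf(rng.uniform(size=n)))

    def mean(self) -> float:
        """Analytic mean of the (untruncated) distribution."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2
        if self.family == "triangular":
            return (p["low"] + p["mode"] + p["high"]) / 3
        if self.family == "normal":
            return p["mean"]
        return math.exp(p["mu"] + p["sigma"] ** 2 / 2)


# -- fitting and goodness of fit -------------------------------------------


def fit_lognormal(samples: Sequence[float]) -> DistributionSpec:
    """Maximum-likelihood lognormal fit (mean/SD of log values, MLE ddof=0)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    if np.any(x <= 0):
        raise ValueError("lognormal support is strictly positive")
    logs = np.log(x)
    sigma = float(np.std(logs, ddof=0))
    if sigma <= 1e-12:  # below fp resolution: the sample is constant
        warnings.warn("degenerate sample: fitted lognormal has sigma = 0")
        sigma = 0.0
    return DistributionSpec.lognormal(float(np.mean(logs)), sigma)


def fit_normal(samples: Sequence[float]) -> DistributionSpec:
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    return DistributionSpec.normal(float(np.mean(x)), float(np.std(x, ddof=0)))


def fit_uniform(samples: Sequence[float]) -> DistributionSpec:
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("degenerate sample: zero range")
    return DistributionSpec.uniform(lo, hi)


def fit_triangular(samples: Sequence[float]) -> DistributionSpec:
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("degenerate sample: zero range")
    # moment-based mode estimate, clipped into the observed range
    mode = float(np.clip(3 * np.mean(x) - lo - hi, lo, hi))
    return DistributionSpec.triangular(lo, mode, hi)


_FITTERS = {
    "lognormal": fit_lognormal,
    "normal": fit_normal,
    "uniform": fit_uniform,
    "triangular": fit_triangular,
}

_CDF_EPS = 1e-12


def anderson_darling(samples: Sequence[float], spec: DistributionSpec) -> float:
    """A² statistic of ``samples`` against the distribution in ``spec``.

    A² = −n − (1/n) Σᵢ (2i−1) [ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))]

    CDF values at exactly 0 or 1 are clamped to ±1e-12 with a warning.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 samples")
    if spec.is_degenerate:
        raise ValueError("Anderson-Darling is undefined against a point distribution")
    f = np.asarray(spec.cdf(x), dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        warnings.warn("CDF reached 0 or 1 at a sample point; clamping")
        f = np.clip(f, _CDF_EPS, 1 - _CDF_EPS)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(f) + np.log1p(-f[::-1])))
    return float(-n - s / n)


def select_distribution(
    samples: Sequence[float], candidates: Sequence[str] = ("normal", "lognormal")
) -> tuple[str, dict[str, float]]:
    """Fit each candidate family by MLE and pick the minimal-A² family.

    Returns ``(best_family, scores)`` where ``scores`` maps every fittable
    candidate to its A² (unfittable candidates get ``inf``).
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate family")
    scores: dict[str, float] = {}
    for fam in candidates:
        if fam not in _FITTERS:
            raise ValueError(f"no fitter for family {fam!r}")
        try:
            spec = _FITTERS[fam](samples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores[fam] = anderson_darling(samples, spec)
        except (ValueError, FloatingPointError):
            scores[fam] = float("inf")
    if all(np.isinf(v) for v in scores.values()):
        raise ValueError("no candidate family could be fitted")
    best = min(scores, key=lambda k: (scores[k], k))
    return best, scores


def substitute_below_mdl(values: np.ndarray, mdl: float) -> np.ndarray:
    """Replace values below the detection limit with MDL/2 (censoring rule)."""
    v = np.asarray(values, dtype=float).copy()
    v[v < mdl] = mdl / 2.0
    return v
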