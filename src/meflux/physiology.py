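"""Growth and substrate-uptake physiology.

Growth rates come from exponential regression of OD600 against time;
specific methanol uptake rates from the depletion of the culture
supernatant relative to a non-consuming evaporation-control culture,
normalized by the biomass integral.  Uncertainties propagate by the
first-order variance formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress

__all__ = [
    "DEFAULT_CDW_FACTOR",
    "TimeSeries",
    "GrowthFit",
    "UptakeEstimate",
    "od_to_cdw",
    "fit_exponential_growth",
    "substrate_rate",
    "specific_uptake_rate",
    "propagate_variance",
]

logger = logging.getLogger(__name__)

#: gCDW L^-1 per OD600 unit for physiology calculations.
DEFAULT_CDW_FACTOR = 0.33


@dataclass(frozen=True)
class TimeSeries:
    """Sampled concentration (mM) or OD600 values at strictly increasing times (h)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "substrate"  # substrate | od

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a time series needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("substrate", "od"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    def at(self, t: float) -> float:
        """Value at time t: exact sample or linear interpolation."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"time {t} outside sampled domain [{self.times[0]}, {self.times[-1]}]"
            )
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class GrowthFit:
    """Exponential-regression result: X(t) = X0 * exp(mu t)."""

    mu: float          # h^-1
    X0: float          # gCDW L^-1
    sigma_mu: float    # standard error of mu, h^-1
    r_squared: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.X0 <= 0:
            raise ValueError("X0 must be positive")


@dataclass(frozen=True)
class UptakeEstimate:
    q: float        # mmol gCDW^-1 h^-1, consumption positive
    sigma_q: float  # same units

    def __post_init__(self) -> None:
        if self.sigma_q < 0:
            raise ValueError("sigma_q must be >= 0")


def od_to_cdw(od: float, factor: float = DEFAULT_CDW_FACTOR) -> float:
    """Convert OD600 to cell dry weight concentration (gCDW L^-1)."""
    if od < 0:
        raise ValueError("OD600 must be >= 0")
    return od * factor


def fit_exponential_growth(
    od_series: TimeSeries, factor: float = DEFAULT_CDW_FACTOR
) -> GrowthFit:
    """Least-squares line on ln(OD) vs time.

    The slope is the specific growth rate mu, the exponentiated intercept
    (times the CDW factor) the initial biomass X0; sigma_mu is the OLS
    standard error of the slope.
    """
    if np.any(od_series.values <= 0):
        raise ValueError("exponential fit requires strictly positive OD values")
    if od_series.times.size < 3:
        raise ValueError("need >= 3 points for a growth fit with an error estimate")
    fit = linregress(od_series.times, np.log(od_series.values))
    return GrowthFit(
        mu=float(fit.slope),
        X0=float(np.exp(fit.intercept) * factor),
        sigma_mu=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
    )


def substrate_rate(series: TimeSeries, t1: float, t2: float) -> float:
    """Finite-difference concentration change rate (s(t2) - s(t1)) / (t2 - t1), mM h^-1."""
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    return (series.at(t2) - series.at(t1)) / (t2 - t1)


def propagate_variance(
    partials: Sequence[float], variances: Sequence[float]
) -> float:
    """First-order (linearized) variance: sum_i (df/dx_i)^2 var_i."""
    partials = np.asarray(partials, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if partials.shape != variances.shape:
        raise ValueError("partials and variances must have equal length")
    if np.any(variances < 0):
        raise ValueError("variances must be >= 0")
    return float((partials**2 * variances).sum())


def specific_uptake_rate(
    culture: TimeSeries,
    evap_control: TimeSeries,
    fit: GrowthFit,
    t1: float,
    t2: float,
    sigma_conc: float = 0.0,
    denominator: str = "integral",
) -> UptakeEstimate:
    """Specific substrate uptake rate over [t1, t2], evaporation-corrected.

    The default ``"integral"`` form divides the abiotic-corrected substrate
    decrease by the exact biomass integral:

        q = (dS_culture - dS_evap) * mu / (X0 * (e^{mu t2} - e^{mu t1}))

    with dS = s(t1) - s(t2) (consumption positive).  ``"midpoint"``
    instead evaluates the instantaneous-biomass denominator
    X0 * e^{mu t} literally at the window midpoint; the two forms agree as
    t2 -> t1.  If mu <= 0 the denominator falls back to the mean biomass
    X0 * (t2 - t1) with a warning.

    ``sigma_conc`` is the measurement standard deviation (mM) of each of
    the four concentration readings; together with ``fit.sigma_mu`` it
    feeds the first-order variance propagation behind ``sigma_q``.
    """
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    if denominator not in ("integral", "midpoint"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    s_c1, s_c2 = culture.at(t1), culture.at(t2)
    s_e1, s_e2 = evap_control.at(t1), evap_control.at(t2)
    delta = (s_c1 - s_c2) - (s_e1 - s_e2)

    def estimate(mu: float) -> float:
        if mu <= 0:
            return delta / (fit.X0 * (t2 - t1))
        if denominator == "integral":
            return delta * mu / (fit.X0 * (math.exp(mu * t2) - math.exp(mu * t1)))
        t_mid = 0.5 * (t1 + t2)
        return delta / (t2 - t1) / (fit.X0 * math.exp(mu * t_mid))

    if fit.mu <= 0:
        logger.warning(
            "non-positive growth rate; using mean-biomass denominator X0*(t2-t1)"
        )
    q = estimate(fit.mu)

    # sensitivities: concentrations enter linearly through delta (prefactor
    # g = q / delta); the mu sensitivity is taken numerically
    if fit.mu <= 0:
        g = 1.0 / (fit.X0 * (t2 - t1))
    elif denominator == "integral":
        g = fit.mu / (fit.X0 * (math.exp(fit.mu * t2) - math.exp(fit.mu * t1)))
    else:
        g = 1.0 / ((t2 - t1) * fit.X0 * math.exp(fit.mu * 0.5 * (t1 + t2)))
    if fit.mu > 0:
        h = max(1e-7, 1e-7 * abs(fit.mu))
        lo = max(fit.mu - h, 1e-12)
        dq_dmu = (estimate(fit.mu + h) - estimate(lo)) / (fit.mu + h - lo)
    else:
        dq_dmu = 0.0
    dq_dconc = g
    var_q = propagate_variance(
        [dq_dconc, dq_dconc, dq_dconc, dq_dconc, dq_dmu],
        [sigma_conc**2] * 4 + [fit.sigma_mu**2],
    )
    return UptakeEstimate(q=q, sigma_q=math.sqrt(var_q))
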