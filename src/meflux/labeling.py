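"""13C isotopologue analytics: labeled fractions and natural-abundance correction.

The average labeled-carbon fraction of an n-carbon metabolite pool with
isotopologue abundances A_0..A_n is

    labeled fraction = sum_i(A_i * i) / (n * sum_i(A_i)),

i.e. the mean number of heavy carbons per molecule divided by the carbon
count.  Measured distributions also contain naturally occurring 13C
(~1.07%); the correction removes it by inverting the binomial mixing
matrix before the fraction is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import comb

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "IsotopologueDistribution",
    "labeled_fraction",
    "correction_matrix",
    "convolve_natural_abundance",
    "natural_abundance_correction",
    "expected_fraction_equimolar",
    "expected_yield_gain_equimolar",
    "round_percent",
]

logger = logging.getLogger(__name__)

#: Natural abundance of 13C.
NATURAL_13C_ABUNDANCE = 0.0107


@dataclass(frozen=True)
class IsotopologueDistribution:
    """M+0 .. M+n abundances (arbitrary intensity units) of an n-carbon pool."""

    metabolite_id: str
    n: int
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "abundances", np.asarray(self.abundances, dtype=float)
        )
        if self.n < 1:
            raise ValueError("carbon count n must be >= 1")
        if self.abundances.shape != (self.n + 1,):
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n + 1} abundances "
                f"(M+0..M+{self.n}), got {self.abundances.shape[0]}"
            )
        if np.any(self.abundances < 0):
            raise ValueError(f"{self.metabolite_id}: negative abundances")
        if self.abundances.sum() <= 0:
            raise ValueError(f"{self.metabolite_id}: all-zero abundances")

    @property
    def total(self) -> float:
        return float(self.abundances.sum())

    def normalized(self) -> np.ndarray:
        return self.abundances / self.total


def labeled_fraction(dist: IsotopologueDistribution) -> float:
    """Average labeled-carbon fraction in [0, 1]; scale-invariant."""
    i = np.arange(dist.n + 1)
    return float((dist.abundances * i).sum() / (dist.n * dist.total))


def correction_matrix(n: int, a: float) -> np.ndarray:
    """Lower-triangular binomial mixing matrix M with observed = M @ true.

    ``M[j, i] = C(n - i, j - i) a^(j - i) (1 - a)^(n - j)``: a molecule
    with i deliberately labeled carbons shows up as M+j when j - i of its
    n - i remaining carbons carry natural 13C.  Invertible for any
    0 <= a < 1 since the diagonal is (1 - a)^(n - i) > 0.
    """
    if not 0 <= a < 1:
        raise ValueError("isotope abundance a must satisfy 0 <= a < 1")
    j, i = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    with np.errstate(invalid="ignore"):
        M = comb(n - i, j - i) * a ** np.maximum(j - i, 0) * (1 - a) ** (n - j)
    return np.where(j >= i, M, 0.0)


def convolve_natural_abundance(
    dist: IsotopologueDistribution, a: float = NATURAL_13C_ABUNDANCE
) -> IsotopologueDistribution:
    """Forward-simulate the natural-abundance smearing of a true distribution."""
    observed = correction_matrix(dist.n, a) @ dist.abundances
    return IsotopologueDistribution(dist.metabolite_id, dist.n, observed)


def natural_abundance_correction(
    dist: IsotopologueDistribution, a: float = NATURAL_13C_ABUNDANCE
) -> IsotopologueDistribution:
    """Remove natural 13C from a measured distribution.

    Solves the triangular system observed = M @ true; small negative
    entries (measurement-noise artifacts) are clipped to zero with a
    warning, and the output is renormalized to the input's total
    intensity.
    """
    if a == 0:
        return IsotopologueDistribution(dist.metabolite_id, dist.n, dist.abundances)
    M = correction_matrix(dist.n, a)
    true = solve_triangular(M, dist.abundances, lower=True)
    if np.any(true < 0):
        clipped = float(-true[true < 0].sum())
        if clipped > 1e-12 * dist.total:
            logger.warning(
                "%s: clipped negative corrected abundances (total %.3g)",
                dist.metabolite_id, clipped,
            )
        true = np.maximum(true, 0.0)
    if true.sum() <= 0:
        raise ValueError(f"{dist.metabolite_id}: correction annihilated the signal")
    true *= dist.total / true.sum()
    return IsotopologueDistribution(dist.metabolite_id, dist.n, true)


def expected_fraction_equimolar(n_from_methanol: int, n_total: int) -> float:
    """Expected labeled fraction when ``n_from_methanol`` of ``n_total``
    carbons derive from (fully labeled) methanol.

    Under equimolar co-assimilation of methanol with a C6 co-substrate each
    hexose unit carries one methanol carbon: ``(1, 6) -> 1/6`` (17% at
    nearest-percent rounding).
    """
    if not 0 <= n_from_methanol <= n_total:
        raise ValueError("need 0 <= n_from_methanol <= n_total")
    return n_from_methanol / n_total


def expected_yield_gain_equimolar(
    n_methanol_carbons: int = 1, n_cosubstrate_carbons: int = 6
) -> float:
    """Relative biomass-yield increase from equimolar methanol co-assimilation.

    Assuming no carbon loss, each mole of co-substrate (C_n) gains
    ``n_methanol_carbons`` biomass carbons, so the maximal biomass rises by
    their carbon ratio: the default C1-on-C6 case gives 1/6, i.e. 17%.
    """
    if n_cosubstrate_carbons < 1 or n_methanol_carbons < 0:
        raise ValueError("carbon counts must be positive")
    return n_methanol_carbons / n_cosubstrate_carbons


def round_percent(fraction: float) -> int:
    """Nearest-integer percent with half-up rounding (0.165 -> 17)."""
    return int(np.floor(fraction * 100.0 + 0.5))
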