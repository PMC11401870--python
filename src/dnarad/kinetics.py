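"""Mass-action kinetics of radiation damage accumulation.

Strand damage is an irreversible first-order loss with two channels:
direct neutron interaction with a nucleotide, and quasi-direct damage
via the hydration-sphere waters.  For strands of length L nucleotides
with hydration ratio theta (waters per nucleotide):

    k_direct = L * integral Phi_bar(E) sigma_nuc(E) dE      [s^-1]
    k_quasi  =     integral Phi_bar(E) sigma_H2O(E) dE      [s^-1 per water]
    per-strand rate = k_direct + k_quasi * theta * L

The undamaged fraction decays as exp(-rate * t) and the strand half-life
is ln(2)/rate.  Indirect (solution-phase radical) damage is excluded:
the storage medium is dry, so k_indirect = 0.  A single recorded
interaction counts the strand as lost (a double-strand break suffices to
prevent recovery); neighbouring base damage is not modelled separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .flux import SECONDS_PER_YEAR, FluxSpectrum, integrate_flux_sigma
from .xsec_model import PiecewiseCubicXSecModel

logger = logging.getLogger(__name__)

__all__ = [
    "DamageKinetics",
    "build_kinetics",
    "surviving_fraction",
    "expected_copies",
    "half_life",
    "SECONDS_PER_YEAR",
]


@dataclass(frozen=True)
class DamageKinetics:
    """Per-strand damage rate decomposition.

    k_direct : s^-1 per strand (already includes the factor L).
    k_quasi : s^-1 per water molecule.
    theta : waters per nucleotide.
    L : nucleotides per strand.
    """

    k_direct: float
    k_quasi: float
    theta: float
    L: int

    def __post_init__(self):
        if self.k_direct < 0 or self.k_quasi < 0:
            raise ValueError("rates must be >= 0")
        if self.theta < 0 or self.L < 1:
            raise ValueError("theta must be >= 0 and L >= 1")

    @property
    def per_strand_rate(self) -> float:
        """Total first-order loss rate per strand, s^-1."""
        return self.k_direct + self.k_quasi * self.theta * self.L


def build_kinetics(
    L: int,
    theta: float,
    flux: FluxSpectrum,
    sigma_nuc: PiecewiseCubicXSecModel,
    sigma_h2o: PiecewiseCubicXSecModel,
) -> DamageKinetics:
    """Assemble per-strand kinetics from flux and cross-section models."""
    return DamageKinetics(
        k_direct=L * integrate_flux_sigma(flux, sigma_nuc),
        k_quasi=integrate_flux_sigma(flux, sigma_h2o),
        theta=theta,
        L=L,
    )


def surviving_fraction(k: DamageKinetics, t: float) -> float:
    """Fraction of strands undamaged after t seconds: exp(-rate * t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return math.exp(-t * k.per_strand_rate)


def expected_copies(C: float, k: DamageKinetics, t: float) -> float:
    """Mean undamaged copy count after t seconds, starting from C."""
    return C * surviving_fraction(k, t)


def half_life(k: DamageKinetics) -> float:
    """Strand half-life ln(2)/rate in seconds; inf for a zero rate."""
    rate = k.per_strand_rate
    if rate <= 0:
        logger.warning("per-strand rate is zero; half-life is infinite")
        return math.inf
    return math.log(2.0) / rate
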