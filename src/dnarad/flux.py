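"""Neutron flux spectra and flux-cross-section integrals.

A :class:`FluxSpectrum` holds a time-averaged differential neutron flux
Phi_bar(E) in neutrons cm^-2 s^-1 eV^-1 on an ascending energy grid (eV).
The built-in reference spectrum is the JESD89A analytic ground-level
atmospheric neutron spectrum normalised to New York City sea level:

    phi(E) [n cm^-2 s^-1 MeV^-1] =
        1.006e-6 * exp(-0.35 ln(E)^2 + 2.1451 ln(E))
      + 1.011e-3 * exp(-0.4106 ln(E)^2 - 0.667 ln(E)),  E in MeV

whose integral above 10 MeV evaluates to ~3.54e-3 n cm^-2 s^-1
(~12.7 n cm^-2 hr^-1).  Integrals of flux times a cross-section model
use trapezoid quadrature on the native grid restricted to the model's
nonzero window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .xsec_model import PiecewiseCubicXSecModel

logger = logging.getLogger(__name__)

__all__ = [
    "FluxSpectrum",
    "jedec_reference",
    "integrate_flux_sigma",
    "load_spectrum",
    "fluence_to_equivalent_time",
    "jedec_differential_flux",
]

CM2_PER_BARN = 1e-24
SECONDS_PER_YEAR = 3.1557e7  # Julian year


@dataclass(frozen=True)
class FluxSpectrum:
    """Differential neutron flux on an energy grid.

    energies : eV, strictly ascending.
    differential_flux : neutrons cm^-2 s^-1 eV^-1 at each grid point.
    """

    energies: np.ndarray
    differential_flux: np.ndarray
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.differential_flux, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("flux grid needs at least two points")
        if f.shape != e.shape:
            raise ValueError("flux and energy grids differ in length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if np.any(f < 0):
            raise ValueError("differential flux must be >= 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "differential_flux", f)

    def scaled(self, factor: float) -> "FluxSpectrum":
        if factor <= 0:
            raise ValueError("scale must be > 0")
        return FluxSpectrum(
            self.energies, self.differential_flux * factor, self.label
        )

    def integrated_flux(self, e_min: float = None, e_max: float = None) -> float:
        """Integral of Phi_bar(E) dE over [e_min, e_max], n cm^-2 s^-1."""
        e, f = self.energies, self.differential_flux
        lo = e[0] if e_min is None else max(e_min, e[0])
        hi = e[-1] if e_max is None else min(e_max, e[-1])
        if hi <= lo:
            return 0.0
        grid = np.unique(np.concatenate([[lo, hi], e[(e > lo) & (e < hi)]]))
        vals = np.interp(grid, e, f)
        return float(np.trapezoid(vals, grid))


def jedec_differential_flux(energy_ev):
    """JESD89A analytic NYC sea-level differential flux, per eV.

    Accepts eV (scalar or array); returns n cm^-2 s^-1 eV^-1.
    """
    E_mev = np.asarray(energy_ev, dtype=float) / 1e6
    ln = np.log(E_mev)
    per_mev = 1.006e-6 * np.exp(-0.35 * ln**2 + 2.1451 * ln) + 1.011e-3 * np.exp(
        -0.4106 * ln**2 - 0.667 * ln
    )
    return per_mev / 1e6


def jedec_reference(scale: float = 1.0, n_points: int = 800) -> FluxSpectrum:
    """Built-in JESD89A ground-level spectrum, NYC sea level, times ``scale``.

    Tabulated on a log-spaced grid covering [1e6, 1e11] eV (the range on
    which the cross-section models are nonzero, plus headroom).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    e = np.logspace(6.0, 11.0, n_points)
    return FluxSpectrum(
        energies=e,
        differential_flux=scale * jedec_differential_flux(e),
        label=f"JESD89A NYC sea level x {scale:g}",
    )


def integrate_flux_sigma(
    flux: FluxSpectrum, model: PiecewiseCubicXSecModel
) -> float:
    """Per-molecule interaction rate = integral Phi_bar(E) sigma(E) dE, s^-1.

    Trapezoid rule on the flux grid restricted to the model's window
    (sigma is zero outside); sigma converted barn -> cm^2.  Returns 0
    with a warning when the grids do not overlap.
    """
    lo, hi = 10.0 ** model.window[0], 10.0 ** model.window[1]
    e = flux.energies
    glo, ghi = max(lo, e[0]), min(hi, e[-1])
    if ghi <= glo:
        logger.warning(
            "flux grid [%g, %g] eV does not overlap model window [%g, %g] eV",
            e[0], e[-1], lo, hi,
        )
        return 0.0
    grid = np.unique(np.concatenate([[glo, ghi], e[(e > glo) & (e < ghi)]]))
    phi = np.interp(grid, e, flux.differential_flux)
    sigma_cm2 = model.predict(grid) * CM2_PER_BARN
    return float(np.trapezoid(phi * sigma_cm2, grid))


def load_spectrum(path: str, label: str = None) -> FluxSpectrum:
    """Read a tabulated spectrum: columns energy_eV, flux_per_cm2_s_eV."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("energy_eV", "flux_per_cm2_s_eV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("energy_eV")
    return FluxSpectrum(
        energies=df["energy_eV"].to_numpy(float),
        differential_flux=df["flux_per_cm2_s_eV"].to_numpy(float),
        label=label or str(path),
    )


def fluence_to_equivalent_time(
    fluence: float, flux: FluxSpectrum, e_min: float = 1e7
) -> float:
    """Exposure time (s) at ``flux`` equivalent to a beam fluence.

    ``fluence`` in n cm^-2; the spectrum is integrated above ``e_min``
    (default 10 MeV, the conventional ground-level accounting cutoff).
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    total = flux.integrated_flux(e_min=e_min)
    if total <= 0:
        raise ValueError(
            f"integrated flux above {e_min:g} eV is zero; cannot form "
            "an equivalent time"
        )
    return fluence / total
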