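"""Per-nuclide neutron cross-section tables.

Tabulated total and elastic cross sections (barn) on an energy grid (eV)
for each chemical element present in the sampled structure.  The quantity
consumed by the Monte Carlo sampler is the *non-elastic* cross section,
approximated as total minus elastic.  Within the tabulated energy range
the non-elastic cross section is linearly interpolated; above the range a
log-linear fit (linear in log10 E vs log sigma) through the two highest
knots is used for extrapolation; below the range the value is zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NuclideCrossSectionTable",
    "CrossSectionLibrary",
    "load_library",
    "CrossSectionFormatError",
    "CrossSectionValidationError",
]

REQUIRED_COLUMNS = ("element", "energy_eV", "total_barn", "elastic_barn")


class CrossSectionFormatError(ValueError):
    """Raised when a cross-section file lacks required columns."""


class CrossSectionValidationError(ValueError):
    """Raised when tabulated values violate physical invariants."""


@dataclass(frozen=True)
class NuclideCrossSectionTable:
    """Total/elastic neutron cross sections vs energy for one element.

    Parameters
    ----------
    element : str
        Chemical symbol (e.g. ``"H"``, ``"O"``).
    energies : ndarray
        Neutron energies in eV, strictly ascending, all positive.
    total : ndarray
        Total cross section in barn at each energy.
    elastic : ndarray
        Elastic cross section in barn at each energy.
    """

    element: str
    energies: np.ndarray
    total: np.ndarray
    elastic: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        t = np.asarray(self.total, dtype=float)
        el = np.asarray(self.elastic, dtype=float)
        if e.ndim != 1 or len(e) < 1:
            raise CrossSectionValidationError(
                f"{self.element}: energy grid must be a non-empty 1-D array"
            )
        if t.shape != e.shape or el.shape != e.shape:
            raise CrossSectionValidationError(
                f"{self.element}: column length mismatch"
            )
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise CrossSectionValidationError(
                f"{self.element}: energies must be strictly increasing and > 0"
            )
        if np.any(el < 0):
            raise CrossSectionValidationError(
                f"{self.element}: negative elastic cross section"
            )
        bad = np.nonzero(t < el)[0]
        if bad.size:
            raise CrossSectionValidationError(
                f"{self.element}: total < elastic at grid row {bad[0]} "
                f"(E={e[bad[0]]:g} eV)"
            )
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "total", t)
        object.__setattr__(self, "elastic", el)

    @property
    def non_elastic_grid(self) -> np.ndarray:
        """Non-elastic cross section (total - elastic) at each knot, barn."""
        return self.total - self.elastic

    def non_elastic(self, energy):
        """Non-elastic cross section at arbitrary energies.

        Linear interpolation inside the grid, log-linear extrapolation
        above it, zero below the lowest knot.  Accepts scalars or arrays;
        returns barn.
        """
        E = np.asarray(energy, dtype=float)
        scalar = E.ndim == 0
        E = np.atleast_1d(E)
        if np.any(E <= 0):
            raise ValueError("energy must be > 0")
        ne = self.non_elastic_grid
        out = np.interp(E, self.energies, ne)
        out[E < self.energies[0]] = 0.0

        above = E > self.energies[-1]
        if np.any(above):
            out[above] = self._extrapolate(E[above])
        out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out

    def _extrapolate(self, E: np.ndarray) -> np.ndarray:
        # Log-linear fit through the two highest knots with nonzero
        # non-elastic; zero if the top knot itself is zero.
        ne = self.non_elastic_grid
        if ne[-1] <= 0:
            return np.zeros_like(E)
        nz = np.nonzero(ne > 0)[0]
        if len(nz) < 2:
            return np.full_like(E, ne[-1])
        i, j = nz[-2], nz[-1]
        x1, x2 = np.log10(self.energies[i]), np.log10(self.energies[j])
        y1, y2 = np.log(ne[i]), np.log(ne[j])
        slope = (y2 - y1) / (x2 - x1)
        # cap the exponent: steep fixture tables would otherwise overflow
        return np.exp(np.minimum(y2 + slope * (np.log10(E) - x2), 700.0))


@dataclass(frozen=True)
class CrossSectionLibrary:
    """Mapping from chemical symbol to its cross-section table."""

    tables: Mapping[str, NuclideCrossSectionTable] = field(default_factory=dict)

    @property
    def elements(self):
        return sorted(self.tables)

    def __contains__(self, element: str) -> bool:
        return element in self.tables

    def table(self, element: str) -> NuclideCrossSectionTable:
        try:
            return self.tables[element]
        except KeyError:
            raise KeyError(
                f"no cross-section table for element {element!r}; "
                f"available: {self.elements}"
            ) from None

    def non_elastic(self, element: str, energy):
        """Non-elastic cross section (barn) for one element at energy (eV)."""
        return self.table(element).non_elastic(energy)

    def require_elements(self, elements) -> None:
        """Raise KeyError unless every element has a table."""
        missing = sorted(set(elements) - set(self.tables))
        if missing:
            raise KeyError(f"cross-section library missing elements: {missing}")


def _read_delimited(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CrossSectionFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}"
        )
    return df[list(REQUIRED_COLUMNS)]


def load_library(path: str) -> CrossSectionLibrary:
    """Load a cross-section library from a delimited file or directory.

    The schema is ``element,energy_eV,total_barn,elastic_barn`` (CSV or
    TSV, auto-detected).  Rows may be unsorted; each element's table is
    sorted by energy.  A directory is read as the concatenation of every
    ``*.csv``/``*.tsv`` file it contains.
    """
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.endswith((".csv", ".tsv", ".txt"))
        )
        if not files:
            raise CrossSectionFormatError(f"{path}: no table files found")
        df = pd.concat([_read_delimited(f) for f in files], ignore_index=True)
    else:
        df = _read_delimited(path)

    tables = {}
    for element, grp in df.groupby("element", sort=True):
        grp = grp.sort_values("energy_eV")
        tables[str(element)] = NuclideCrossSectionTable(
            element=str(element),
            energies=grp["energy_eV"].to_numpy(float),
            total=grp["total_barn"].to_numpy(float),
            elastic=grp["elastic_barn"].to_numpy(float),
        )
    return CrossSectionLibrary(tables=tables)
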