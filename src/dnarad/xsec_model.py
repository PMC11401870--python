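"""Piecewise cubic cross-section model sigma(E) and its Poisson fit.

The non-elastic cross section of a nucleotide (or water molecule) is
modelled as log sigma = beta0 + beta1*x + beta2*x^2 + beta3*x^3 with
x = log10(E/eV) on the window x in [6, 10]; outside the window sigma is
taken as zero (interactions there are marginal).  The model is fit to
Monte Carlo hit counts by Poisson regression with a log link and an
exposure offset log(n_impacts * n_molecules / sample_area_barn), so the
linear predictor is log sigma in barn.  Published reference coefficients
for nucleotide and water responses ship as module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .mc import BARN_PER_NM2, CrossSectionEstimate

__all__ = [
    "PiecewiseCubicXSecModel",
    "CovariateFitResult",
    "predict_sigma",
    "fit_piecewise",
    "covariate_test",
    "REFERENCE_NUC",
    "REFERENCE_H2O",
]


@dataclass(frozen=True)
class PiecewiseCubicXSecModel:
    """sigma(E) = exp(cubic in log10 E) on [1e6, 1e10] eV, else 0 barn."""

    beta: Tuple[float, float, float, float]
    window: Tuple[float, float] = (6.0, 10.0)
    outside_value: float = 0.0  # barn
    beta_se: Optional[Tuple[float, float, float, float]] = None
    response: str = ""

    def predict(self, energy):
        """Evaluate sigma (barn) at energies in eV (scalar or array)."""
        E = np.asarray(energy, dtype=float)
        scalar = E.ndim == 0
        E = np.atleast_1d(E)
        if np.any(E <= 0):
            raise ValueError("energy must be > 0")
        x = np.log10(E)
        b0, b1, b2, b3 = self.beta
        sigma = np.exp(b0 + b1 * x + b2 * x**2 + b3 * x**3)
        lo, hi = self.window
        sigma = np.where((x >= lo) & (x <= hi), sigma, self.outside_value)
        return float(sigma[0]) if scalar else sigma

    def scaled(self, factor: float) -> "PiecewiseCubicXSecModel":
        """Model with sigma multiplied by ``factor`` (shifts beta0)."""
        b0, b1, b2, b3 = self.beta
        return PiecewiseCubicXSecModel(
            beta=(b0 + float(np.log(factor)), b1, b2, b3),
            window=self.window,
            outside_value=self.outside_value * factor,
            response=self.response,
        )

    def to_dict(self):
        return {
            "beta": list(self.beta),
            "window": list(self.window),
            "outside_value": self.outside_value,
            "link": "log",
            "response": self.response,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            beta=tuple(d["beta"]),
            window=tuple(d.get("window", (6.0, 10.0))),
            outside_value=float(d.get("outside_value", 0.0)),
            response=d.get("response", ""),
        )


# Reference coefficients for the per-nucleotide and per-water non-elastic
# neutron cross-section models (log sigma/barn vs log10 E/eV), with the
# reported standard deviations of each coefficient.
REFERENCE_NUC = PiecewiseCubicXSecModel(
    beta=(-201.8137711, 72.93892997, -8.51321887, 0.32227953),
    beta_se=(127.0, 10.4, 1.33, 5.64e-2),
    response="nucleotide",
)
REFERENCE_H2O = PiecewiseCubicXSecModel(
    beta=(-400.1662991, 144.52231949, -17.1973897, 0.67101674),
    beta_se=(159.0, 59.9, 7.46, 0.308),
    response="water",
)


def predict_sigma(model: PiecewiseCubicXSecModel, energy):
    """Functional alias for :meth:`PiecewiseCubicXSecModel.predict`."""
    return model.predict(energy)


@dataclass(frozen=True)
class CovariateFitResult:
    """Two-sided t test of one exogenous regression term."""

    covariate: str
    coefficient: float
    stderr: float
    tstat: float
    pvalue: float
    dof: int


def _design(estimates: Sequence[CrossSectionEstimate], response: str):
    """Counts, cubic design matrix and exposure offset inside the window."""
    rows = [
        e
        for e in estimates
        if 6.0 <= np.log10(e.energy) <= 10.0 and not e.degenerate
    ]
    if len(rows) < 4:
        raise ValueError(
            f"need >= 4 estimates with E in [1e6, 1e10] eV, got {len(rows)}"
        )
    x = np.log10([e.energy for e in rows])
    if response == "nucleotide":
        counts = np.array([e.hits_nucleotide for e in rows], dtype=float)
        n_mol = np.array([e.n_nucleotides_in_area for e in rows], dtype=float)
    elif response == "water":
        counts = np.array([e.hits_water for e in rows], dtype=float)
        n_mol = np.array([e.n_waters_in_area for e in rows], dtype=float)
    else:
        raise ValueError("response must be 'nucleotide' or 'water'")
    if np.any(n_mol <= 0):
        raise ValueError(f"some estimates have no {response} molecules in area")
    n_imp = np.array([e.n_impacts for e in rows], dtype=float)
    area_barn = np.array([e.sample_area for e in rows]) * BARN_PER_NM2
    offset = np.log(n_imp * n_mol / area_barn)
    X = np.column_stack([np.ones_like(x), x, x**2, x**3])
    return rows, counts, X, offset


def _fit_glm(counts, X, offset):
    import statsmodels.api as sm

    if np.all(counts == 0):
        raise ValueError("all hit counts are zero; cross section degenerate")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"{X.shape[0]} observations cannot identify {X.shape[1]} parameters"
        )
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset)
    return model.fit(use_t=True)


def fit_piecewise(
    estimates: Sequence[CrossSectionEstimate], response: str = "nucleotide"
) -> PiecewiseCubicXSecModel:
    """Fit the piecewise cubic sigma(E) model to MC estimates.

    Observations with energies outside [1e6, 1e10] eV are excluded.
    Poisson regression of hit counts with exposure offset; the returned
    model carries the coefficient standard errors in ``beta_se``.
    """
    _, counts, X, offset = _design(estimates, response)
    res = _fit_glm(counts, X, offset)
    return PiecewiseCubicXSecModel(
        beta=tuple(res.params),
        beta_se=tuple(res.bse),
        response=response,
    )


def covariate_test(
    estimates: Sequence[CrossSectionEstimate],
    covariate: str = "thickness",
    response: str = "nucleotide",
) -> CovariateFitResult:
    """Refit the cubic model plus one linear exogenous term.

    ``covariate`` is ``"thickness"`` (nm) or ``"gc_fraction"``.  Returns
    the term's two-sided t test (residual degrees of freedom).
    """
    rows, counts, X, offset = _design(estimates, response)
    if covariate == "thickness":
        z = np.array([e.thickness for e in rows], dtype=float)
    elif covariate == "gc_fraction":
        z = np.array([e.gc_fraction for e in rows], dtype=float)
    else:
        raise ValueError("covariate must be 'thickness' or 'gc_fraction'")
    if np.ptp(z) == 0:
        raise ValueError(f"covariate {covariate!r} is constant across estimates")
    Xz = np.column_stack([X, z])
    res = _fit_glm(counts, Xz, offset)
    return CovariateFitResult(
        covariate=covariate,
        coefficient=float(res.params[-1]),
        stderr=float(res.bse[-1]),
        tstat=float(res.tvalues[-1]),
        pvalue=float(res.pvalues[-1]),
        dof=int(res.df_resid),
    )
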