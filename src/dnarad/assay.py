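"""Validation-assay statistics: qPCR curves, trend tests, error rates.

Covers the experimental side of the damage model: four-parameter
logistic (4PL) fits of qPCR amplification curves with extraction of
C_half (the cycle at half the maximum amplification achieved), ordinary
least-squares trend tests of a per-sample statistic against neutron
fluence, per-base insertion/deletion/substitution error rates from
read-vs-reference alignment counts, and the copy-number arithmetic
converting a qPCR concentration to molecule counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .xsec_model import CovariateFitResult

__all__ = [
    "AmplificationCurve",
    "FourPLFit",
    "ErrorRateRecord",
    "SampleQuant",
    "NonAmplificationError",
    "FitError",
    "fit_4pl",
    "trend_test",
    "per_base_error_rates",
    "alignment_counts",
    "copies_from_mass",
    "AVOGADRO",
]

AVOGADRO = 6.022e23
DALTON_PER_BP = 650.0  # mean molecular weight of a DNA base pair, g/mol
REFERENCE_BP = 310.0  # amplicon length used in the copy-number formula
DILUTION_FACTOR = 100.0


class NonAmplificationError(ValueError):
    """Curve shows no amplification (flat or decreasing fluorescence)."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or produced an unusable curve."""


@dataclass(frozen=True)
class AmplificationCurve:
    """One qPCR trace: cycle index vs fluorescence, with its fluence."""

    sample_id: str
    fluence: float  # n cm^-2
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cycles, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("cycles and fluorescence must be equal-length 1-D")
        if np.any(np.diff(c) <= 0):
            raise ValueError("cycles must be strictly increasing")
        object.__setattr__(self, "cycles", c)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters and the half-maximum cycle C_half.

    y = d + (a - d) / (1 + (x/c)^b): a is the low-cycle floor, d the
    plateau, c the midpoint cycle, b the slope.
    """

    a: float
    b: float
    c: float
    d: float
    c_half: float
    residual_rms: float = float("nan")


def _four_pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(curve: AmplificationCurve) -> FourPLFit:
    """Least-squares 4PL fit of an amplification curve.

    C_half is the cycle where the fitted curve crosses halfway between
    the fitted floor and the maximum *observed* fluorescence.  Raises
    :class:`NonAmplificationError` for flat or decreasing curves and
    :class:`FitError` on non-convergence.
    """
    x, y = curve.cycles, curve.fluorescence
    if len(x) < 8:
        raise ValueError("need at least 8 cycles to fit a 4PL curve")
    span = y.max() - y.min()
    if span <= 0 or span <= 1e-12 * max(abs(y.max()), 1.0):
        raise NonAmplificationError(f"{curve.sample_id}: flat fluorescence")
    n4 = max(2, len(y) // 4)
    if y[-n4:].mean() <= y[:n4].mean():
        raise NonAmplificationError(
            f"{curve.sample_id}: fluorescence does not increase"
        )
    p0 = (y.min(), 1.0, float(np.median(x)), y.max())
    try:
        popt, _ = curve_fit(_four_pl, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"{curve.sample_id}: 4PL fit failed: {exc}") from exc
    a, b, c, d = (float(v) for v in popt)
    target = (a + float(y.max())) / 2.0
    c_half = _invert_4pl(a, b, c, d, target, x)
    if not (x.min() <= c_half <= x.max()):
        raise FitError(
            f"{curve.sample_id}: C_half {c_half:.2f} outside observed "
            f"cycle range [{x.min():g}, {x.max():g}]"
        )
    resid = y - _four_pl(x, a, b, c, d)
    return FourPLFit(
        a=a, b=b, c=c, d=d,
        c_half=float(c_half),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _invert_4pl(a, b, c, d, target, x):
    # closed-form inverse where defined; bisection on the fitted curve
    # as a fallback for sign conventions that break the algebra
    ratio = (a - d) / (target - d) - 1.0
    if ratio > 0 and c > 0:
        try:
            return c * ratio ** (1.0 / b)
        except (ValueError, ZeroDivisionError, OverflowError):
            pass
    f = lambda t: _four_pl(t, a, b, c, d) - target
    lo, hi = float(x.min()), float(x.max())
    if f(lo) * f(hi) > 0:
        raise FitError("fitted curve never reaches half-maximum")
    return brentq(f, lo, hi)


def trend_test(
    values: Sequence[float],
    fluences: Sequence[float],
    name: str = "fluence",
) -> CovariateFitResult:
    """Two-sided t test of the slope of statistic vs fluence (OLS).

    The acceptance criterion used throughout is p < 0.05, uncorrected.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    x = np.asarray(fluences, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and fluences must be equal-length 1-D")
    if len(y) < 3:
        raise ValueError("need at least 3 samples for a trend test")
    if np.ptp(x) == 0:
        raise ValueError("fluence is constant; no trend is identifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CovariateFitResult(
        covariate=name,
        coefficient=float(res.params[1]),
        stderr=float(res.bse[1]),
        tstat=float(res.tvalues[1]),
        pvalue=float(res.pvalues[1]),
        dof=int(res.df_resid),
    )


@dataclass(frozen=True)
class ErrorRateRecord:
    """Per-base error rates for one sample (errors per aligned ref base)."""

    sample_id: str
    fluence: float
    insertion_rate: float
    deletion_rate: float
    substitution_rate: float

    def __post_init__(self):
        for r in (self.insertion_rate, self.deletion_rate, self.substitution_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def total_rate(self) -> float:
        return self.insertion_rate + self.deletion_rate + self.substitution_rate


def per_base_error_rates(
    alignments: pd.DataFrame,
    sample_id: str = "",
    fluence: float = 0.0,
) -> ErrorRateRecord:
    """Aggregate alignment operation counts into per-base error rates.

    ``alignments`` has one row per read with integer columns ``matches``,
    ``mismatches``, ``insertions``, ``deletions``.  Rates are normalised
    by the total aligned reference bases (matches + mismatches +
    deletions, the reference-consuming operations).
    """
    required = ("matches", "mismatches", "insertions", "deletions")
    for col in required:
        if col not in alignments.columns:
            raise ValueError(f"alignment table missing column {col!r}")
    tot = alignments[list(required)].sum()
    ref_bases = float(tot["matches"] + tot["mismatches"] + tot["deletions"])
    if ref_bases <= 0:
        raise ValueError("zero aligned reference bases")
    return ErrorRateRecord(
        sample_id=sample_id,
        fluence=fluence,
        insertion_rate=float(tot["insertions"]) / ref_bases,
        deletion_rate=float(tot["deletions"]) / ref_bases,
        substitution_rate=float(tot["mismatches"]) / ref_bases,
    )


def alignment_counts(read: str, reference: str) -> dict:
    """Global (Needleman-Wunsch) alignment operation counts.

    Unit match/mismatch/gap scores; returns a dict with ``matches``,
    ``mismatches``, ``insertions`` (bases in read not in reference),
    ``deletions`` and ``ref_len``.  Intended for synthetic test reads;
    production pipelines should supply counts from a real aligner.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(reference, read)[0]
    matches = mismatches = insertions = deletions = 0
    ref_blocks, read_blocks = aln.aligned
    prev_r = prev_q = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        deletions += r0 - prev_r
        insertions += q0 - prev_q
        for rc, qc in zip(reference[r0:r1], read[q0:q1]):
            if rc == qc:
                matches += 1
            else:
                mismatches += 1
        prev_r, prev_q = r1, q1
    deletions += len(reference) - prev_r
    insertions += len(read) - prev_q
    return dict(
        matches=matches,
        mismatches=mismatches,
        insertions=insertions,
        deletions=deletions,
        ref_len=len(reference),
    )


@dataclass(frozen=True)
class SampleQuant:
    """Copy-number arithmetic for one qPCR-quantified sample.

    mass m = 100 * c * V0 (dilution factor 100); copies
    N_c = 6.022e23 * m / (310 * 650 * 1e9), i.e. mass over the molar
    mass of a 310 bp duplex at 650 g/mol/bp, with m in nanograms.
    """

    concentration: float
    template_volume: float
    dilution_factor: float
    mass: float
    copies: float


def copies_from_mass(
    c: float, V0: float, dilution_factor: float = DILUTION_FACTOR
) -> SampleQuant:
    """Apply the mass and copy-number formulas to a concentration reading."""
    if c < 0 or V0 < 0:
        raise ValueError("concentration and volume must be >= 0")
    m = dilution_factor * c * V0
    copies = AVOGADRO * m / (REFERENCE_BP * DALTON_PER_BP * 1e9)
    return SampleQuant(
        concentration=c,
        template_volume=V0,
        dilution_factor=dilution_factor,
        mass=m,
        copies=copies,
    )
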