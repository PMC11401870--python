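"""Time-to-information-loss model for a DNA data storage pool.

Each unique sequence starts with C physical copies, every copy failing
independently at the per-strand hazard k (s^-1).  The copy count is a
pure-death process; the sequence is lost when the count drops below the
detection limit C_LLOD.  The loss time is therefore a sum of independent
exponential stage times with rates lambda(c) = c*k for c = C, ..., C_LLOD
— a hypoexponential distribution.  Numerically the CDF is evaluated
through the equivalent order-statistic identity

    P[T_loss <= t] = P[Binomial(C, e^{-kt}) <= C_LLOD - 1]

which is stable for copy numbers up to 1e6, where the textbook
sum-of-exponentials product formula overflows; the textbook form is kept
as a small-C oracle.  The pool of N i.i.d. sequences loses information at
the minimum of the per-sequence loss times, giving the pool CDF
1 - (1 - F(t))^N and an expected loss time computed by quadrature of the
pool survival function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "PoolDesign",
    "strand_loss_cdf",
    "hypoexponential_cdf",
    "expected_strand_loss_time",
    "pool_loss_cdf",
    "pool_survival",
    "expected_pool_loss_time",
    "simulate_pool",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class PoolDesign:
    """Storage-scheme parameters.

    N : unique sequences in the pool.
    C : initial physical copies per sequence.
    L : strand length in nucleotides.
    theta : residual waters per nucleotide.
    C_LLOD : copy count below which a sequence is unrecoverable.
    """

    N: int
    C: int
    L: int = 150
    theta: float = 4.0
    C_LLOD: int = 10

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.C_LLOD < 0 or self.C <= self.C_LLOD:
            raise ValueError("need C > C_LLOD >= 0")
        if self.L < 1 or self.theta < 0:
            raise ValueError("L must be >= 1 and theta >= 0")

    @property
    def stage_counts(self) -> np.ndarray:
        """Copy counts c = C_LLOD, ..., C indexing the exponential stages."""
        return np.arange(self.C_LLOD, self.C + 1)


def strand_loss_cdf(d: PoolDesign, k: float, t):
    """P[one sequence is lost by time t] (binomial-tail form).

    Loss means the undamaged copy count has fallen to C_LLOD - 1, i.e.
    at least C - C_LLOD + 1 of the C copies have failed by t.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    p_alive = np.exp(-k * t)
    out = stats.binom.cdf(d.C_LLOD - 1, d.C, p_alive)
    return float(out) if out.ndim == 0 else out


def hypoexponential_cdf(rates, t, dps: int = 60):
    """Textbook hypoexponential CDF for distinct rates (small-stage oracle).

    CDF(t) = 1 - sum_i [prod_{j != i} lam_j/(lam_j - lam_i)] e^{-lam_i t}.
    The alternating weights grow combinatorially (~1e13 already for 20
    stages), so the sum is evaluated in ``dps``-digit arithmetic via
    mpmath and rounded at the end.  Practical up to a few dozen stages;
    used as an independent cross-check of :func:`strand_loss_cdf`.
    """
    import mpmath

    lam = np.asarray(rates, dtype=float)
    if lam.ndim != 1 or lam.size < 1:
        raise ValueError("rates must be a 1-D sequence")
    if np.any(lam <= 0) or len(np.unique(lam)) != lam.size:
        raise ValueError("rates must be positive and distinct")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    ts = np.atleast_1d(t_arr)
    with mpmath.workdps(dps):
        lams = [mpmath.mpf(float(x)) for x in lam]
        weights = []
        for i, li in enumerate(lams):
            w = mpmath.mpf(1)
            for j, lj in enumerate(lams):
                if j != i:
                    w *= lj / (lj - li)
            weights.append(w)
        cdf = np.array(
            [
                float(
                    1
                    - mpmath.fsum(
                        w * mpmath.e ** (-li * mpmath.mpf(float(tv)))
                        for w, li in zip(weights, lams)
                    )
                )
                for tv in ts
            ]
        )
    cdf = np.clip(cdf, 0.0, 1.0)
    return float(cdf[0]) if scalar else cdf


def expected_strand_loss_time(d: PoolDesign, k: float) -> float:
    """E[T_loss^n] = sum_{c=C_LLOD}^{C} 1/(c k) = (H_C - H_{C_LLOD-1})/k."""
    if k <= 0:
        raise ValueError("k must be > 0")
    if d.C_LLOD == 0:
        raise ValueError(
            "C_LLOD = 0 implies an absorbing stage with zero rate; the "
            "expected loss time is infinite"
        )
    return float(special.digamma(d.C + 1) - special.digamma(d.C_LLOD)) / k


def pool_survival(d: PoolDesign, k: float, t):
    """P[no sequence lost by t] = (1 - F_strand(t))^N, computed stably."""
    F = strand_loss_cdf(d, k, t)
    return np.exp(d.N * np.log1p(-np.minimum(F, 1.0 - 1e-16)))


def pool_loss_cdf(d: PoolDesign, k: float, t):
    """P[information lost from the pool by t] = 1 - (1 - F(t))^N."""
    return 1.0 - pool_survival(d, k, t)


def expected_pool_loss_time(d: PoolDesign, k: float) -> float:
    """E[T_loss] = integral of the pool survival function over [0, inf).

    The integrand is rescaled by the closed-form single-sequence mean so
    the transition region sits near 1, then integrated adaptively.
    """
    m = expected_strand_loss_time(d, k)
    val, _ = integrate.quad(
        lambda u: float(pool_survival(d, k, m * u)),
        0.0,
        np.inf,
        limit=400,
    )
    return m * val


def simulate_pool(d: PoolDesign, k: float, n_reps: int, rng_seed=None):
    """Pure-death (Gillespie) simulation of pool loss times.

    For every replicate, each of the N sequences steps its copy count
    from C down through C_LLOD with exponential stage times of rate c*k;
    the pool loss time is the minimum over sequences.  Returns an array
    of n_reps loss times (s).  Deterministic given ``rng_seed``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rates = d.stage_counts * k  # (S,)
    out = np.empty(n_reps)
    # chunk replicates to bound the (reps, N, stages) draw size
    max_elems = 20_000_000
    chunk = max(1, int(max_elems / (d.N * rates.size)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        e = rng.standard_exponential((m, d.N, rates.size))
        strand_times = (e / rates).sum(axis=2)
        out[done : done + m] = strand_times.min(axis=1)
        done += m
    return out


def sensitivity_sweep(
    baseline: PoolDesign,
    parameter: str,
    grid,
    flux,
    sigma_nuc,
    sigma_h2o,
) -> pd.DataFrame:
    """E[T_loss] as one design parameter varies from baseline.

    ``parameter`` is one of ``N``, ``C``, ``L``, ``theta``.  The
    per-strand hazard is rebuilt for every grid point (it depends on L
    and theta).  Returns a DataFrame with columns ``parameter``,
    ``value``, ``expected_loss_time_s`` and ``error`` (empty string, or
    the message for grid points violating the design invariants).
    """
    from .kinetics import build_kinetics

    if parameter not in ("N", "C", "L", "theta"):
        raise ValueError("parameter must be one of N, C, L, theta")
    records = []
    for value in grid:
        fields = dict(
            N=baseline.N,
            C=baseline.C,
            L=baseline.L,
            theta=baseline.theta,
            C_LLOD=baseline.C_LLOD,
        )
        fields[parameter] = (
            float(value) if parameter == "theta" else int(value)
        )
        try:
            design = PoolDesign(**fields)
            kin = build_kinetics(
                design.L, design.theta, flux, sigma_nuc, sigma_h2o
            )
            et = expected_pool_loss_time(design, kin.per_strand_rate)
            records.append(
                dict(parameter=parameter, value=value,
                     expected_loss_time_s=et, error="")
            )
        except ValueError as exc:
            records.append(
                dict(parameter=parameter, value=value,
                     expected_loss_time_s=np.nan, error=str(exc))
            )
    return pd.DataFrame.from_records(records)
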