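# Methods

## Scope and model structure

`dnarad` models the loss of information from a dehydrated DNA data
storage pool caused by atmospheric neutron radiation. The chain has four
layers: (i) geometric Monte Carlo estimation of per-molecule non-elastic
neutron cross sections from an atomic structure; (ii) a parametric
σ(E) model fit to those estimates; (iii) mass-action damage kinetics
under a flux spectrum; (iv) a first-passage (pure-death) model of the
time until any sequence's copy count falls below the detection limit.
Validation-side statistics (qPCR 4PL fits, trend tests, per-base error
rates) mirror the analyses used in accelerated-irradiation experiments.

Only neutrons are treated. Muons interact too weakly to matter, and the
charged secondaries (protons, alphas) have cross sections one to four
orders of magnitude smaller, so a neutron-only treatment is a
conservative simplification for ordinary storage environments; where
heavy-nuclide surroundings generate significant secondaries, the flux
input should be adjusted rather than the model.

## Cross-section Monte Carlo

**Inputs.** A DNA-plus-water structure (PDB, explicit hydrogens
expected) or a synthetic lattice; per-element tables of total and
elastic cross sections vs energy. The non-elastic cross section is
total − elastic, linearly interpolated inside the tabulated grid and
extrapolated log-linearly (linear in log₁₀E vs log σ through the two
highest nonzero knots) above it; below the grid it is taken as zero,
which is inconsequential because the fitted σ(E) model is zero below
1 MeV anyway.

**Slab construction.** The unit cell is stacked along z until the target
thickness is reached. Each appended copy receives independent rotations
about x, y, z ~ U[0, 2π), applied about the cell centroid in that order,
and x/y translations ~ U[−10%, 10%] of the cell edge lengths, emulating
an amorphous film. Pivot and order are not physically constrained; the
centroid/x-y-z choice is fixed for reproducibility. PDB coordinates are
Å/10; no crystallographic symmetry expansion is performed — the deposited
asymmetric unit is taken as the cell. Structures without hydrogens are
accepted with a logged warning (adding hydrogens is an external,
well-solved problem; their non-elastic contribution is small).

**Sampling.** Impact points are uniform on a 1 nm² axis-aligned square
centred at the slab's projected centroid. For each point the nearest
nucleus in the 2-D projection is found (k-d tree; exact ties go to the
lowest atom index, a measure-zero rule); an interaction is recorded when
the point lies inside the disk of area σ_elem(E) around that nucleus.
Points inside the disk of a *non-nearest* nucleus do not count — a
deliberate, documented approximation of the projection scheme. Hits are
attributed to the nucleus's category, and

σ̂ = hits × A / (n_impacts × n_molecules-in-square), A = 1 nm² = 10¹⁰ barn,

which is exact for a single isolated nucleus and equals Σσ/A-normalised
coverage for non-overlapping disks. Molecules are counted as distinct
residues with at least one atom projecting into the square.

## σ(E) model and regression

σ(E) = exp(β₀ + β₁x + β₂x² + β₃x³) with x = log₁₀(E/eV) on x ∈ [6, 10]
and σ = 0 outside. The out-of-window value is set to 0 barn (not
exp(0) = 1 barn): interactions outside the window are marginal, and a
1-barn floor would dominate the flux integrals spuriously.

Fitting is Poisson regression of raw hit counts with the natural-log
link and exposure offset log(n_impacts × n_molecules / A_barn), so the
linear predictor is log σ in barn. This is the canonical formulation for
count data with known exposure and reproduces weighted least squares on
log σ̂ in the large-count limit; the exact response/weighting behind the
bundled reference coefficients is not recoverable from their source, so
coefficient-level agreement with a refit of the original simulation data
is not asserted anywhere. Covariate tests (slab thickness, GC fraction)
add one linear exogenous term to the same design and report its
two-sided t statistic at the residual degrees of freedom
(n_obs − 5; e.g. 165 observations → t(160)).

Reference coefficients (log σ/barn vs log₁₀E/eV):

| | β₀ | β₁ | β₂ | β₃ |
|---|---|---|---|---|
| nucleotide | −201.8137711 | 72.93892997 | −8.51321887 | 0.32227953 |
| water | −400.1662991 | 144.52231949 | −17.1973897 | 0.67101674 |

## Flux spectra and kinetics

The built-in reference spectrum is the JESD89A analytic ground-level
atmospheric neutron spectrum normalised to New York City sea level,

φ(E)[n·cm⁻²s⁻¹MeV⁻¹] = 1.006×10⁻⁶ e^(−0.35 ln²E + 2.1451 lnE)
 + 1.011×10⁻³ e^(−0.4106 ln²E − 0.667 lnE), E in MeV,

tabulated on a log grid over [10⁶, 10¹¹] eV. Its integral above 10 MeV
evaluates to ≈3.54×10⁻³ n·cm⁻²s⁻¹ (≈12.7 n·cm⁻²hr⁻¹); dividing a beam
fluence of 5.1×10¹¹ n/cm² by it gives ≈4.6 million years of sea-level
exposure, consistent (within ~4%) with the ~4.4 million years quoted for
such irradiation campaigns. The >10 MeV cutoff is the conventional
ground-level accounting and is configurable.

Rate integrals ∫Φ̄(E)σ(E)dE use trapezoid quadrature on the flux grid
restricted to the σ window (σ = 0 outside), barn → cm²; spectra are
point values of differential flux, not histogram bins. Grid refinement
beyond the 800-point default changes results by < 0.1%.

Kinetics: k_direct = L∫Φ̄σₙᵤ꜀dE, k_quasi = ∫Φ̄σ_H₂OdE, per-strand rate
k = k_direct + k_quasi·θ·L. Indirect (solution-phase radical) damage is
zero under dry storage. Any recorded interaction counts the strand as
lost — a double-strand break alone suffices to prevent recovery, so
neighbouring base damage is not modelled separately. Half-life is
ln 2 / k. Years are Julian (3.1557×10⁷ s).

**Computed half-life vs the published figure.** With the reference
coefficients, the NYC sea-level spectrum, L = 150 and θ = 4, the model
gives t₁ᐟ₂ ≈ 4.3×10¹⁵ years. The published half-life of 4.9×10⁷ years
for this setting is not derivable from the printed coefficients and any
stated sea-level flux via the half-life formula — the gap is roughly
eight orders of magnitude. The package therefore reports its own
computed value and this comparison rather than reproducing the printed
number; both values support the same qualitative conclusion (radiation
is not a practical threat), but the discrepancy is documented instead of
being hidden by calibration.

## Loss-time model

Copy counts follow a pure-death process with per-copy hazard k: stage
rates λ(c) = c·k for c = C down through C_LLOD (inclusive — loss occurs
when the count drops *below* C_LLOD). The per-sequence loss time is the
hypoexponential sum of the stage times. The implementation evaluates its
CDF through the order-statistic identity
P[T ≤ t] = P[Binomial(C, e^(−kt)) ≤ C_LLOD − 1], which is stable up to
C ~ 10⁶, where the textbook sum-of-exponentials form overflows. The
textbook form is retained as a small-C oracle; because its alternating
weights grow combinatorially (~10¹³ at 20 stages), the oracle is
evaluated in 60-digit arithmetic (mpmath) so the cross-check is
meaningful at the 10⁻¹⁰ level.

E[T per strand] = Σ 1/(ck) = (H_C − H_{C_LLOD−1})/k via digamma.
Pool CDF = 1 − (1 − F)^N (i.i.d. sequences), computed with log1p for
stability; E[T_loss] integrates the pool survival function by adaptive
quadrature after rescaling time by the closed-form strand mean so the
transition region sits near 1. C_LLOD defaults to 10 copies, a
representative detection limit for amplification-plus-sequencing
recovery; it is scheme-dependent and should be adjusted per scheme. The
Gillespie simulator draws the stage-time sums directly and takes the
pool minimum; it is chunked to bound memory.

Default study conditions for sensitivity sweeps are the baseline design
N = 7373, C = 1000, L = 150, θ = 4, C_LLOD = 10 under the JESD89A
spectrum; sweeps vary one parameter at a time and rebuild the hazard
where it depends on L or θ.

## Assay statistics

qPCR curves are fit to y = d + (a − d)/(1 + (x/c)^b) by least squares
(initialised a = min, d = max, c = median cycle, b = 1). C½ is the cycle
where the *fitted* curve crosses halfway between the fitted floor and
the maximum *observed* fluorescence — the most literal reading of "half
the maximum amplification achieved"; it must fall inside the observed
cycle range. Flat or non-increasing curves raise a non-amplification
error. Trend tests are OLS of the per-sample statistic on fluence with
a two-sided t on the slope (df = n − 2; 6 samples → t(4)), uncorrected
p < 0.05.

Per-base error rates divide summed insertion/deletion/substitution
operation counts by summed aligned *reference* bases (matches +
mismatches + deletions). Alignment is consumed as precomputed counts
from any standard aligner; a global Needleman–Wunsch helper with unit
match/mismatch/gap scores (Biopython `PairwiseAligner`) is provided for
synthetic reads. Copy-number arithmetic: m = 100·c·V₀ (dilution factor
100) and N_c = 6.022×10²³·m/(310·650·10⁹).

## Synthetic data

The fixture generators produce: regular lattices with exactly known
areal density, optional alternating GC labels and a configurable
hydration ratio (default fixtures use 3.83 waters per nucleotide, the
hydration of the dodecamer crystal structure the sampling scheme is
built around); smooth per-element cross-section tables; 4PL qPCR curves
at the experimental fluence ladder 0–5.1×10¹¹ n/cm² with 1% plateau
noise and an optional injected fluence effect (zero by default — the
no-effect null); and reads with independent per-base error rates.
Ground truth goes to sidecar JSON files. These fixtures emulate the
*geometry and statistics* of real inputs, not their chemistry: lattice
cells are not real duplex structures, synthetic tables are not evaluated
nuclear data, and simulated reads have no sequencing-quality structure.
Passing tests therefore demonstrate correctness of the estimators and
closed forms, not agreement with any particular experimental dataset.

## Numerical choices and degenerate inputs

- Impact sampling is chunked (2²⁰ points) to bound memory at 10⁸-impact
  production scales; tests and the acceptance script use 10⁴–10⁶ impacts,
  where the binomial-error analysis makes the expected precision explicit.
- A sampling square containing no molecules yields zero estimates with a
  degeneracy flag rather than an exception; such rows are excluded from
  fits.
- Zero per-strand rate gives an infinite half-life with a warning.
- Empty flux/σ window overlap integrates to zero with a warning.
- Exact nearest-distance ties break to the lowest atom index.
- Extrapolation exponents are capped to avoid float overflow on
  adversarial fixture tables.

## Known limitations

- No particle transport: no scattering angles, energy deposition, or
  secondary cascades; shadowing between stacked layers is ignored except
  through the nearest-nucleus rule.
- The Poisson formulation of the reference fit is a reconstruction; the
  bundled coefficients are used as constants, and exact refit agreement
  is not claimed.
- The i.i.d. assumption across sequences ignores shared synthesis biases;
  C_LLOD as a constant ignores scheme-level logical redundancy.
- Real aligner behaviour (affine gaps, clipping) is not reproduced by the
  unit-score helper; error rates from different aligners will differ in
  ambiguous regions.
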