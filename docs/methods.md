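# Methods

This note records the models implemented in `gqmelt`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices a user auditing results should know about.

## Sequential multi-state melting model

Unfolding is modelled as a chain of two-state steps
N ⇌ I₁ ⇌ … ⇌ U.  Each step i has a van't Hoff enthalpy ΔHᵢ and a
midpoint Tm,ᵢ, with the free-energy parameterization
ΔGᵢ(T) = ΔHᵢ(1 − T/Tm,ᵢ), i.e. ΔSᵢ = ΔHᵢ/Tm,ᵢ.  The step constant is

    Kᵢ(T) = exp[(|ΔHᵢ|/R)(1/Tm,ᵢ − 1/T)],  R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹,

with all temperatures converted °C → K (T + 273.15) at the boundary of
the thermodynamic code.  Species weights are cumulative products of the
Kᵢ and populations are their normalized fractions, evaluated via
log-sum-exp so arbitrarily sharp steps and extreme temperatures cannot
overflow.  |ΔH| controls transition sharpness; enthalpies are stored
with whatever sign the user supplies (melting tables in this field are
often quoted negative) and used as |ΔH| internally.

Melting observable: a matrix A with the spectral variable along rows
and temperature along columns, so A = E Fᵀ for species spectra E and
populations F.  Inference proceeds by

1. **SVD** A = U S Vᵀ (numpy economy SVD; factors carry unit-norm
   columns, singular values descending).
2. **Rank selection.** The first-order autocorrelation
   C(v) = Σ vᵢvᵢ₊₁ of each unit-normalized V column is compared with a
   cutoff (defaults 0.8 for CD, 0.7 for UVRR); the selected rank is the
   *leading contiguous* block of passing components — a later component
   that happens to pass after one fails is treated as noise.  The
   variance explained is 100·Σ_{k≤rank} s_k²/Σ s_k².  Autocorrelation
   is computed on unit-norm vectors; for an n-point constant vector it
   equals (n−1)/n, so cutoffs should be read against series length.
3. **Global fit.** With rank r = m+1 retained profiles, the model is
   V_r ≈ F(θ)·C with θ = (|ΔHᵢ|, Tm,ᵢ) shared and C free.  C is solved
   by linear least squares at every θ (variable projection), so the
   nonlinear optimizer (scipy trust-region reflective, bounds
   |ΔH| ∈ [1, 500] kcal/mol) sees only 2m parameters.  Midpoints are
   parameterized as (Tm,₁, positive increments) which enforces
   ascending order and removes label switching; the minimum increment
   is 0.5 °C.  By default each profile's residual is weighted by its
   singular value — equivalently the fit minimizes the Frobenius error
   of the rank-truncated data matrix.  Under iid spectral noise the
   noise level in profile j scales as 1/s_j, so this weighting is the
   maximum-likelihood choice; it measurably stabilizes the weakest
   component's contribution.  Unweighted fitting
   (`weight_by_singular_values=False`) reproduces the plain
   profile-space objective.  Standard errors are asymptotic
   (χ²-scaled inverse Gauss–Newton Hessian), with the Tm errors
   propagated through the increment reparameterization.
4. **Species spectra.** E = U_r S_r Cᵀ, so that A ≈ E Fᵀ.  A nearly
   singular C (two species sharing a profile shape) is flagged with a
   warning rather than an error.

Fit initialization defaults to inflection temperatures: the derivative
screen takes single-wavelength profiles, applies a central-difference
derivative and a light moving average, and reports local extrema above
20% of the derivative maximum; when it yields fewer candidates than
steps the midpoints start evenly spread over the temperature range,
with |ΔH| = 40 kcal/mol per step.

## Raman band decomposition

Each spectrum in the 1000–1800 cm⁻¹ window is modelled as a constant or
linear baseline plus k Gaussians (non-negative amplitudes; resonance
Raman bands point up).  "As few bands as the data support" is
operationalized as BIC minimization over k when the count is not given.
Band "intensity" is reported as peak height (amplitude), with the area
amplitude·σ·√(2π) also emitted, since the two conventions differ only
by the width factor.  Series tracking fits columns in temperature
order, warm-starting each fit at the previous column's centers, which
follows slow drifts (e.g. the B band's 1578 → 1574 cm⁻¹ downshift on
tetrad melting) without label switching; a failed column is recorded
as a NaN gap and the series continues.  Bands converging to within
2 cm⁻¹ of each other are flagged as degenerate.

## Small-angle scattering

**Form factors.** The parallelepiped form factor is the standard
double orientation average with Φ(x) = sin(x)/x amplitudes, evaluated
by fixed-order Gauss–Legendre quadrature on [0, π/2]² (default order
76 per angle; an order-doubling test shows ≤ 1e-8 relative change over
Q ≤ 1 Å⁻¹ for the geometries of interest, and the analytic identity
"gap-0 axial dimer = double-height box" holds to machine precision).
The dimer is two identical boxes displaced by D = c+gap along the
height axis (default, the end-to-end sandwich geometry) or a+gap along
a base edge; per orientation the coherent pair contributes
|A|²·(1 + cos(qDu)) with u the displacement direction cosine, and the
result is normalized to P(0) = 1.

**Mixture.** I(q) = scale·[(1−f_d)P_mono + 2f_d·P_dimer] + background.
f_d is the fraction of quadruplex *units* residing in dimers; with
number density n of units there are n·f_d/2 dimers of squared volume
(2V)², hence the weight 2f_d.  A single scale is shared by both
populations.  The weighted fit (lmfit) bounds f_d to [0, 1] through the
optimizer's internal variable transform and reports asymptotic errors
and reduced χ².  Because the χ² surface has local minima along a
(height, dimer-fraction) ridge, the fit first runs a coarse grid
pre-search over (a, c, f_d) with scale and background projected out
linearly, then refines from the best node; this made recovery of a
half-dimerized synthetic sample exact in the median where a plain
bounded fit stalled at f_d ≈ 0.28.  The fit's internal quadrature
default is order 40, machine-accurate for boxes up to ~100 Å over the
study window; larger particles should pass a higher order.

**Guinier.** ln I = ln I₀ − q²Rg²/3 fitted by weighted linear
regression, iteratively re-selecting the window q ≤ qRg_max/Rg
(default qRg_max = 1.3) until stable.  For strongly elongated
particles the law bends before qRg = 1.3 and qRg_max ≈ 1.0 is the
appropriate restriction.

**Porod invariant.** Q* = ∫₀^∞ q²I dq from the data (trapezoid),
extended below q_min by the Guinier model and above q_max by a fitted
A/q⁴ tail (tail window: last 15% of points; extension pieces are
reported separately for audit).  V = 2π²I₀/Q* is scale-invariant and
assumes a monodisperse two-phase particle; on analytic curves it
recovers the sphere volume within ~0.2% and the 15×15×27 Å box within
~0.5% (the box's corners violate the smooth-surface assumption more
strongly, hence the looser 10% test band).

**Indirect Fourier transform.** p(r) is expanded on `nbins` (default
50) cubic B-splines over [0, Dmax] with the endpoint basis functions
removed, enforcing p(0) = p(Dmax) = 0.  Coefficients minimize
χ²[I_model − I] + α∫p″² with I_model(q) = 4π∫p(r)·sin(qr)/(qr) dr
(kernel assembled on a 301-point r grid).  Non-negativity is *not*
imposed.  `alpha="auto"` scans 12 decades and takes the usable corner
of the L-curve in its discrepancy-constrained form: the largest α whose
misfit is statistically indistinguishable from the best attainable
(χ²_red ≤ max(1, 1.2·min χ²_red)).  Naive curvature maximization on
this problem's L-curve lands on its degenerate tails and was rejected.
Rg and I(0) come from the moments of p; χ²_red > 5 sets a "Dmax too
small" flag.  Dmax itself is a required user input (or scan): the
inversion cannot choose it.

**Scalar models.** The SAW chain law Rg = A₀N^ν defaults to A₀ = 3 Å
and ν = 0.62, the values established for unfolded single-stranded
oligonucleotides; at N = 22 it gives 20.4 Å.  Molecular weight uses
average internal residue masses (A 313.21, C 289.18, G 329.21,
T 304.20 g/mol) with the free-acid 5′-OH end correction −61.96 g/mol;
the particle volume is v̄·MW/N_A with v̄ = 0.55 ml/g by default, the
partial specific volume usually assumed for G-quadruplexes.  The
absolute forward cross section is I(0) = n_p·V_p²·Δρ²; contrast Δρ is a
user input (no scattering-length computation from composition).

## Synthetic data: what it emulates and what it does not

Melting matrices are A = E Fᵀ + ε with ε iid Gaussian (additive,
constant variance — the detector-noise regime of CD/UVRR), on the
protocols of the emulated experiments: CD 220–325 nm, 30–82 °C step
2 °C; UVRR 1000–1800 cm⁻¹, 30–90 °C step 4 °C.  The bundled
three-step CD parameters (|ΔH| = 27.3/41.0/63.2 kcal/mol,
Tm = 38.5/60.3/68.9 °C) and two-step UVRR parameters
(34.5/72.6 kcal/mol, 44.5/71.4 °C) are the reference thermodynamics of
the free telomeric quadruplex in K⁺.  Default noise in the examples
and tests is 2% of the peak species amplitude.

Species spectra are Gaussian-mixture cartoons placed at the canonical
band positions (CD hybrid fold: +290, +270 shoulder, −233 nm; Raman
bands A/B/C and the 1370 cm⁻¹ thymine band) — qualitative shapes, not
quantitative CD/Raman predictions.  The intermediates additionally
carry marker bands in spectral regions where the native and unfolded
spectra are weak.  This is deliberate: the basis must be genuinely
four-dimensional (CD) or three-dimensional (UVRR) with the weakest
component above the few-percent noise floor, because that is the
detectability regime in which a four-species analysis of real melting
data operates; without it the synthetic system would pose a different
(unsolvable) problem than the one the method addresses.  Consequences
for interpretation: passing recovery tests shows the inference chain is
correct and efficient *given* species distinct enough to detect — it
does not show that any particular real data set contains four
detectable species.

Scattering curves are mixture intensities with multiplicative Gaussian
noise (σ = noise_frac·I, the counting-dominated regime) on
Q = 0.02–1 Å⁻¹; at noise_frac = 0 the intensities are exact and a
nominal 1% σ is attached so the curve remains usable in weighted fits.
Not emulated anywhere: instrument smearing/resolution, interparticle
structure factors, buffer-subtraction residuals, wavelength-dependent
CD noise, and cosmic-ray spikes in Raman columns.

All generators are bitwise deterministic given (spec, seed); every
randomized test fixes its seeds (0–9 for the recovery ensembles).

## Degenerate inputs and tie-breaks

Zero vectors are rejected by the autocorrelation; a rank-0 selection
(nothing passes the cutoff) warns and returns 0 rather than raising;
populations at a step midpoint are exactly (…, ½, ½, …); Gaussian band
fits reject windows outside the stored axis; the Guinier fit refuses
curves with a non-decreasing low-q trend and windows that collapse
below 5 points; the Porod integral refuses non-positive intensities
after background subtraction; p(r) results with non-positive integral
warn and report Rg = NaN.

## Problem sizes

The recovery ensembles used throughout (10 seeds; 106×27 CD and
201×16 UVRR matrices; 120-point scattering curves) run the full test
suite in well under a minute of pure computation; they are the sizes at
which the estimators' medians are stable, and larger ensembles change
the reported medians only in the third digit.

## Known limitations

* The sequential scheme is the only melting topology; branched or
  parallel intermediates are out of scope by design.
* CD and UVRR matrices are fitted separately; no joint multi-probe fit.
* Asymptotic standard errors ignore the (small) coupling between the
  projected linear coefficients and the thermodynamic parameters.
* The Porod volume degrades for particles whose form factor deviates
  from q⁻⁴ within the measured window (unfolded chains), mirroring the
  physical limitation of the invariant.
* No instrument-level corrections (desmearing, detector sensitivity,
  absolute-scale calibration) — inputs are assumed reduced.
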