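# Methods

## Model

All observables derive from one two-site exchange parameterization per
sample condition: populations (p_G, p_E), total exchange rate k_ex, state
chemical shifts (ω_G, ω_E), per-state longitudinal and transverse
relaxation rates (R₁, R₂) and optional paramagnetic contributions (Γ₁, Γ₂).
The forward rates k_GE = p_E·k_ex and k_EG = p_G·k_ex satisfy detailed
balance by construction.  Interfaces take shifts and fields in Hz; the
evolution matrices work in rad/s internally.

### Forward models

* **CEST.** The magnetization vector (E/2, Ix, Iy, Iz per state) is
  propagated under a 7×7 evolution matrix for the saturation time t_CEST at
  every offset.  The identity row carries the thermal-correction terms
  2R₁p that return each state's z magnetization to its equilibrium
  population; the saturation field ω₁ = 2π·B1 acts from y.  The per-state
  offsets entering the matrix are (state shift − saturation carrier), so a
  dip appears when the carrier sits on a resonance; a symmetry test pins
  this sign convention.  Profiles are normalized by the mean intensity at
  the far off-resonance reference offsets (±10 kHz by default), and the
  normalization fails loudly if the reference itself is saturated.
  Propagation uses a stacked eigendecomposition across the offset grid
  (one LAPACK call) with an automatic fallback to the scaling-and-squaring
  matrix exponential wherever the eigenbasis is ill-conditioned; tests
  assert agreement between the two routes to 1e−10 and against fine-step
  ODE integration to 1e−6.
* **CPMG.** The constant-time echo train is n = T·ν repeats of
  (τ−180−2τ−180−τ), τ = 1/(4ν), with ideal instantaneous pulses.
  `simulate_cpmg` evaluates the exact solution in the manner of Baldwin's
  closed form: analytic eigen-propagators of the 2×2 complex
  free-precession matrix, the per-cycle propagator
  U = P(τ)·conj(P(2τ))·P(τ), and Uⁿ by binary exponentiation.
  R₂,eff = −(1/T)·ln(I/I₀) with the ground-state coherence as the
  observable and I₀ = p_G (the reference experiment without the relaxation
  delay).  `simulate_cpmg_numeric` repeats the calculation segment by
  segment with scipy's expm and explicit conjugation pulses and serves as
  the cross-check.  The exact solution ripples by a few s⁻¹ at frequencies
  where only one or two cycles fit into T_CPMG; dispersions are strictly
  non-increasing only in the many-cycle regime, and the tests assert
  exactly that plus R₂,eff(ν_max) ≤ R₂,eff(ν_min).  Ground- and
  excited-state plateau rates are tied by default (`assume_shared_R2`).
* **EXSY.** Auto/cross intensities are S·exp(K·t_ZZ)·diag(p_G, p_E) with K
  the 2×2 longitudinal exchange-relaxation matrix; total z magnetization is
  conserved when R₁ = 0.
* **Inversion recovery.** The 3-vector (E/2, Iz_G, Iz_E) starts inverted,
  (1/2, −p_G, −p_E), and recovers under the 3×3 matrix whose thermal terms
  are 2(R₁+Γ₁)p; the observable is Iz_G + Iz_E, reaching +1 (times scale)
  at long delays.  The equilibrium-looking initial vector sometimes quoted
  for this experiment would produce a constant signal; the inverted start
  is what an inversion-recovery sequence prepares.
* **1D lineshape.** Steady-state two-site spectrum
  I(ω) = S·|Re(Σ(M⁻¹·I₀))| with the 2×2 complex matrix containing
  −R₂(−Γ₂)+i(ω_state−ω) on the diagonal and the exchange rates off it,
  evaluated by the closed-form 2×2 inverse vectorized over the axis.

### PRE physics

Γ₁ and Γ₂ follow the Solomon–Bloembergen equations with only the nuclear
Larmor frequency in the spectral density (electron-frequency terms are
neglected, as is standard for nitroxides), using the model-free
J(ω) with 1/τ_c = 1/τ_R + 1/τ_s and 1/τ_t = 1/τ_R + 1/τ_s + 1/τ_i.
Constants: µ₀ = 1.257×10⁻⁶ N·A⁻², γ_I = 251.815×10⁶ rad·T⁻¹s⁻¹ (¹⁹F),
g = −2.002, µ_B = −9.285×10⁻²⁴ J·T⁻¹, s = 1/2, ω_I = 2π·471 MHz.
Distances are accepted in Å and converted to metres internally.

The inversion (Γ₁, Γ₂) → (r, S², τ_i) runs a multi-start trust-region
least-squares on (log r, logit S², log τ_i) with log-space residuals.  One
rate pair gives 2 equations for 3 unknowns and is flagged underdetermined;
pairs measured in complexes with different τ_R (100 ns for the nine-subunit
core, 140 ns with the catalytic subunit) make the system overdetermined and
generically unique.  Distinct near-optimal minima are reported, not
silently resolved; an irreducible residual flags infeasibility — e.g.
Γ₂/Γ₁ < 7/6 is impossible because J(0) ≥ J(ω_I).

A note on the Γ₁/Γ₂ asymmetry: lowering S² from 0.7 to 0.1 at fixed r
(τ_R = τ_s = 100 ns, τ_i = 1 ns) *enhances* Γ₁ (J(ω_I) grows with internal
motion) while Γ₂ *drops* (J(0) ∝ S²τ_c dominates it).  The assertable form
used in the tests is the enhancement inequality
Γ₁(0.1)/Γ₁(0.7) > 1 > Γ₂(0.1)/Γ₂(0.7); a naive "larger relative change"
statement would be false here because the Γ₂ decrease is itself large at
S² = 0.1.

## Global fit

Each dataset carries a role→parameter-name map; datasets that name the
same parameter share it, which encodes the study's assumptions (probe
shifts shared across complexes and RNA states; per-complex populations and
rates; RNA-bound conditions hard-wired to 100% open via their condition
tag; per-dataset scales; per-condition relaxation rates).  Shift parameters
are expressed in Hz at the 471 MHz reference field and rescaled by the
field ratio for dispersion data recorded at other fields, so one shared
shift serves both spectrometers.

χ² is minimized with Nelder–Mead (the `fminsearch` family) on transformed
coordinates — logit for populations, log for rates, times and scales — so
box constraints hold without a constrained optimizer.  The simplex is
restarted once from its best vertex; termination combines a parameter
tolerance of 1e−6 in transformed space with a function tolerance taken
relative to the χ² scale, so convergence does not depend on the units of
σ.  Fits are deterministic given identical data and start values.

Uncertainties are parametric bootstrap: replicates are drawn as best-fit
prediction + Gaussian(0, σ_i), start values jittered uniformly by ±5%, and
the model refit; the per-parameter SD, full sample distributions and
2.5/16/50/84/97.5% quantiles are reported (the distributions need not be
Gaussian).  Whether the original analysis resampled residuals or
parametric noise is not specified by its description; parametric resampling
was chosen for consistency with the σ-driven χ².  A single top-level seed
fans out to per-replicate seeds; failed replicates are excluded and
counted.

## Deconvolution

Overlapped resonances (a main peak with a shoulder from a second,
non-interconverting conformation) are fit as a sum of two absorptive
Lorentzians; components are ordered by descending area and the fit is
flagged degenerate when the centres are closer than a quarter of the
summed half-widths.  For inversion-recovery series the positions and
widths are frozen and only the two amplitudes are fit per delay (a linear
least-squares), followed by a mono-exponential recovery fit per component;
a component with no amplitude excursion is flagged indeterminate rather
than assigned a rate.

## Synthetic studies

The generator reproduces the published acquisition grids exactly: 67 CEST
offsets from −2450 to +2450 Hz referenced at ±10 kHz, t_CEST = 0.4 s, B1
of 10–25 Hz; constant-time CPMG with T = 10 ms and ν up to 5000 Hz in
integer-cycle steps at 471 and 565 MHz; the 12 EXSY mixing delays from 1
to 600 ms; the printed inversion-recovery delay lists.  Generating truths
are the published values where printed (p_E = 5% / k_ex = 5800 s⁻¹ fast
regime; p_E = 26% / k_ex = 35 s⁻¹ slow regime; 100% open with RNA;
S² ≈ 0.1 open / 0.7 closed; τ_R = 100/140 ns; τ_s = 100 ns) and documented
placeholders elsewhere: the state shift separation is set to 2 ppm at
471 MHz (940 Hz), intrinsic R₁ ≈ 0.8–1 s⁻¹ and R₂ ≈ 105–120 s⁻¹ are typical
for a CF₃ probe on a very large complex, the closed-state label distance
uses the 6.8 Å NMR scale and the open state a remote 12 Å, and τ_i = 2 ns.
Each preset's `provenance` dict marks every truth as published or
placeholder.

Noise is homoscedastic Gaussian per experiment at σ = signal_scale/SNR
(SNR 200 for CEST and CPMG intensities, 100 for inversion recovery, 50 for
EXSY and spectra — chosen as realistic for ¹⁹F detection of a ~1 MDa
complex at NMR concentrations).  CPMG noise is injected on the surviving
intensities exp(−R₂,eff·T) and propagated back, giving the physically
correct heteroscedastic R₂,eff errors.  What the generator does *not*
emulate: raw FIDs, baseline/phase artifacts, heteroscedastic spectral
noise, pulse imperfections, or a third conformation — passing recovery
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to model violation.

## Problem sizes and numerical choices

The recovery studies fit 493 points / 9 free parameters (slow regime) and
174 points / 8 free parameters (fast regime); the bootstrap demonstrations
use an EXSY+IR configuration (59 points, 5 free parameters) with 200
replicates.  Matrix exponentials are scipy's scaling-and-squaring except
for the stacked-eigendecomposition CEST path described above; degenerate
2×2 eigen-propagators fall back to a first-order expansion; k_ex = 0 with
p_E > 0 (two static species) is allowed since the deconvolution analysis
assumes exactly that.

## Limitations

Two-site models only; no finite-pulse or off-resonance CPMG effects; no
Curie-spin or cross-correlated PRE terms; no ensemble PRE back-calculation
from coordinates; no model selection machinery.  The structural utilities
compare Cα–Cα distances to NMR label–label distances only through the
±13 Å label-arm interval (7 Å CF₃ arm + 6 Å nitroxide arm) and make no
attempt to model label conformers explicitly.
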