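# Methods

## Two-site exchange model

A backbone ¹⁵N nucleus exchanging between a major state A (population
`p_A = 1 − p_B`) and a minor state B at rate `k_ex = k_AB + k_BA`, with a
¹⁵N chemical-shift difference `Δω` (stored in ppm and converted per field
as `Δω(rad/s) = dw · 2π · ν_H(MHz) · 0.10137`, the ¹⁵N/¹H
gyromagnetic-ratio magnitude), relaxes under CPMG with an effective rate
`R₂,eff(ν_CPMG)` computed two ways:

- **Closed form** (`backend="closed_form"`): the Carver–Richards
  expression with a single intrinsic rate `R₂⁰` shared by both states
  (per field).  With equal intrinsic rates this expression is not an
  approximation to the asymptotic observable: it equals the dominant-
  eigenvalue decay rate of the two-echo cycle propagator to machine
  precision, which we verified numerically across the fitted parameter
  ranges.  A log-space branch handles the `cosh` overflow at very low
  pulsing rates.
- **Numerical oracle** (`backend="numerical"`): explicit propagation of
  the 2×2 complex Bloch–McConnell matrix through the pulse train.  The
  train has `n = 2·T_relax·ν_CPMG` refocusing intervals
  (`ν_CPMG = 1/(2δ)`, δ the spacing between 180° pulse centres,
  `T_relax = 40 ms` by default); each 180° pulse conjugates the
  coherences, and `R₂,eff = −ln(|M_A(T)|/p_A)/T_relax` starting from
  equilibrium populations.  Echo pairs compose to a linear map, so the
  train is evaluated with a matrix power.  Non-integer `2·T·ν` is rounded
  to the nearest pulse count with a warning.

Two finite-train effects matter when comparing the backends and are easy
to mistake for model error.  First, rounding the pulse count changes the
effective `ν_CPMG` (at 33.3 Hz with a 40 ms train the error is 12%).
Second, the finite train carries a startup/readout transient — the
initial condition projects onto both eigenmodes of the cycle propagator —
which perturbs the extracted rate by up to a few s⁻¹ at high `p_B` and
decays as `1/T_relax`.  Oracle-agreement checks therefore use CPMG
frequencies commensurate with the train and `T_relax = 0.6 s`; under
those conditions the closed form and the propagation agree within
0.16 s⁻¹ over a grid spanning `p_B ≤ 0.15`, `k_ex` 300–6000 s⁻¹, `dw ≤ 6`
ppm at both fields.  At experimental train lengths the transient is real
physics shared by data and any explicit-propagation fitter; since both
our generator and our fitter use the closed form, fitted parameters are
unaffected.

`R_ex` is defined throughout as `R₂,eff(33.3 Hz) − R₂,eff(1000 Hz)`, the
difference between the lowest and highest CPMG frequencies of the
experiment.  `R₂,eff(ν)` is monotone non-increasing wherever dispersion
data can exist (R_ex below the detection limit); in slow exchange with
large `Δω` the profile develops genuine local bumps (confirmed with the
numerical oracle), but such residues are exchange-broadened beyond
detection and never fit.

## Dispersion fitting

Per-residue fits share `(p_B, k_ex, dw)` across both static fields with
one `R₂⁰` per field; region-global fits additionally tie `(p_B, k_ex)`
across all member residues, each keeping its own `dw` and `R₂⁰`.  The
model of one population and one rate per contiguous region encodes
cooperative partial unfolding of a protein stretch.

Numerical choices:

- Weighted least squares (`scipy.optimize.least_squares`, trust-region
  reflective) with bounds `p_B ∈ [0.001, 0.3]`, `k_ex ∈ [50, 10⁴] s⁻¹`,
  `dw ∈ [0.1, 12] ppm`, `R₂⁰ ∈ [0.1, 200] s⁻¹`.  The bounds comfortably
  cover the 2–15% populations and hundreds-to-thousands s⁻¹ rates the
  generator produces, and keep the optimiser out of the very-slow-
  exchange regime where the closed form is least reliable.
- Deterministic multi-start over `k_ex ∈ {200, 500, 1000, 2000, 4000}` ×
  `p_B ∈ {0.01, 0.05, 0.15}` (starting `dw = 2 ppm`, `R₂⁰ = min R₂,eff`);
  lowest χ² wins and ties resolve to the smaller `p_B`, so a flat curve
  is explained by the least exchange.
- Parameter uncertainties by seeded parametric Monte-Carlo: refitting
  noise-perturbed copies of the best-fit curves (150 draws by default,
  restarted at the best fit).  This remains honest for parameters near a
  bound, where covariance-matrix estimates are not.
- Residues whose dispersion amplitude is below twice the point noise are
  still fit but flagged `no_significant_dispersion` rather than being
  force-fit against the `p_B` bound.

Classification and segmentation: a residue is dynamic when its fitted
`R_ex` at 600 MHz exceeds 3 s⁻¹ or its peak is broadened beyond
detection.  Region extraction replaces by-eye inspection of the R_ex
profile with an explicit rule: maximal runs of dynamic residues
tolerating gaps of at most 2 intervening non-dynamic (quiescent,
unassigned or proline) residues, minimum 3 dynamic members.  The rule is
idempotent and invariant to input ordering.

## Fast relaxation and tumbling

`R₁`, `R₂` and the heteronuclear NOE are computed from rigid isotropic
rotor spectral densities `J(ω) = (2/5)·τ_c/(1+(ωτ_c)²)` with the standard
¹⁵N–¹H constants `r_NH = 1.02 Å` and `Δσ = −160 ppm` (order parameter 1).
The correlation time is inverted per residue from
`τ_c = sqrt(6·R₂/R₁ − 7)/(4π·ν_N)`, the large-molecule limit obtained by
dropping the high-frequency spectral-density terms; for a 13–15 ns dimer
at 600 MHz that approximation biases τ_c by about −0.8%, inside the 2%
round-trip tolerance.  The estimate is a 10% trimmed mean over residues
surviving three filters: NOE ≥ 0.65 (removes flexible termini),
`R₂/R₁ ≥ 7/6` (the formula's validity floor), and absence from the
exchange-flag set, since `R_ex` inflates `R₂` and biases τ_c upward.  The
trimmed mean alone absorbs a few contaminated residues; when ~40% of the
chain carries exchange (the quiescent-dimer profile), explicit flagging
is required and demonstrably removes the bias.

## Monomer–dimer equilibrium

For `2M ⇌ D` with `K_a = [D]/[M]²` (molar convention; identical in value
to the mass-concentration form `½·M·C_d/C_m²` with `M` the monomer
molecular weight, default 12 800 g/mol), mass balance gives
`C_m = (−1 + sqrt(1 + 8·K_a·c))/(4·K_a)` at monomer-equivalent total
concentration `c = C_T(mg/mL)/M`; a series branch avoids cancellation at
small `K_a·c`.  The observed ellipticity is the mole-fraction-weighted
sum of the monomer and dimer signals.  `fit_ka` profiles `K_a` in log
space over `[10³, 10⁹] M⁻¹` by decade-spaced multi-start nonlinear least
squares and bootstraps the titration points (200 seeded resamples) for a
95% CI.  A titration whose fitted monomer and dimer ellipticities differ
by less than three times the residual noise raises an explicit
identifiability error.

Identifiability limits: over the experimental concentration window
0.05–3.0 mg/mL the monomer plateau of a `K_a = 10⁶ M⁻¹` titration lies
below the lowest measurable point, so only ~25% of the full
monomer–dimer amplitude is sampled.  Noise levels are therefore
meaningfully quoted relative to the *observed* signal range; at 5% of
that range the median recovered `log₁₀K_a` over replicates stays within
0.2 of truth, whereas noise at 5% of the full amplitude makes `K_a ≥ 10⁶`
unidentifiable on this grid (we verified the scatter is a property of
the global optimum by profiling `K_a` with exact linear solves for the
ellipticities, not an optimiser artifact).

The dilution control `dilution_effect` reports the relative percent
increase in monomer mole fraction upon dilution; for a two-fold dilution
it is bounded by `100·(√2 − 1) ≈ 41.4%`, approached in the strong-dimer
limit, and evaluates to 40.9% at `K_a = 10⁶ M⁻¹`, 1.5 mM.

## Structure comparison

Superposition is closed-form least squares (Kabsch via SVD) on atoms
matched by (chain, residue id, atom name), replacing maximum-likelihood
superposition: deterministic and adequate for RMS reporting.  The
alignment subset and the RMS-reporting subset can differ (align on a
framework, measure everything).  Near-collinear alignment selections are
flagged.  Hydrogen bonds use geometric criteria — N/O donor to N/O
acceptor, heavy-atom distance ≤ 3.5 Å, D–H⋯A angle ≥ 120° whenever the
donor hydrogen is present in the model; an oxygen with no attached
hydrogen is not allowed to donate, a nitrogen is (crystal-style models
often lack hydrogens).  Bond lengths are donor–acceptor distances; diffs
match bonds by their atom keys and report length changes above 0.1 Å.
Interface membership replaces buried-surface-area analysis with a
distance contact: a residue is interfacial when any heavy atom lies
within 5 Å (configurable) of the partner chain.  Residue ids are strings
throughout, supporting insertion codes; alternate locations keep the
highest-occupancy conformer.

## Synthetic data generator

The generator emulates the study system — a dimeric 114-residue domain
with residue ids 1–113 plus the insertion-code position "27d" and six
prolines (8, 40, 43, 59, 80, 95) carrying no amide — under three
profiles.  Regions 1–9, 35–60 and 88–102 each receive one shared
`(p_B, k_ex)` pair (`k_ex` uniform in 1000–2500 s⁻¹) and per-residue `dw`;
`p_B = 0` outside regions.  LEN-like draws `p_B` in 0.02–0.04 and `dw` in
1–3 ppm (τ_c 13.5 ns); SMA-like draws `p_B` in 0.08–0.15 and `dw` in
1.5–5 ppm (τ_c 15.0 ns), which pushes a substantial fraction of region
residues past the detection limit; quenched sets `p_B = 0` everywhere.
Intrinsic rates are 12/13 s⁻¹ (600/800 MHz) with 0.5 s⁻¹ per-residue
jitter.  The default CPMG grid is 12 points from 33.3 to 1000 Hz at both
fields; dispersion noise defaults to σ = 0.3 s⁻¹ per point (real
per-point noise varies by instrument and sample; this configurable
default makes a 3 s⁻¹ R_ex a ≈10σ amplitude).  A residue whose noise-free `R_ex` at the lower
field exceeds the detection limit (default 25 s⁻¹, chosen so the
SMA-like profile loses its loop residues) is recorded as broadened
beyond detection and yields no dispersion or relaxation data.  All
generators are deterministic in their seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: peak overlap and partial assignment,
anisotropic tumbling, temperature/field-dependent intrinsic rates,
off-resonance and pulse-imperfection effects, monomer–dimer exchange
contributions to dispersion, residue-to-residue variation in `p_B`
within a region, and baseline/concentration errors in CD.  Recovery
statistics quoted here are for Gaussian noise at the stated levels.

## Problem sizes

The shipped test suite and analysis scripts run at desk scale by design:
dispersion recovery studies use 100 noisy replicates of a single residue
plus a four-residue region; the pipeline run fits ~70 detectable
residues at two fields; the oracle comparison uses 100 parameter sets ×
2 fields × 6 CPMG frequencies; CD recovery uses 10-point titrations × 50
replicates.  Monte-Carlo uncertainty draws default to 150 (fits) and 200
(bootstrap).

## Known limitations

- The Carver–Richards form assumes equal intrinsic rates in the two
  states; distinct `R₂⁰(A)/R₂⁰(B)` are not modelled.
- Three-site exchange, off-resonance R₁ρ and proton CPMG are out of
  scope, as are model-free order parameters and anisotropic diffusion.
- `Δω` signs are unidentifiable from CPMG alone and stored as
  magnitudes.
- The hydrogen-bond detector is purely geometric; it does not type
  side-chain chemistry beyond the element and presence of hydrogens.
- Structure comparison operates on user-supplied coordinate models; no
  mutant modelling or energy minimisation is performed.
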