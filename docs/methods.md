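# Methods

This note documents the models, the numerical choices behind them, and
what the synthetic-data tests do and do not establish.

## System and scope

The package analyses the salt-induced compaction of a strongly charged,
fully disordered polyanion — an aspartic/glutamic acid-rich protein of
N = 506 residues with ~212 acidic and ~65 basic residues (binary-scheme
net charge −147 e; the physiological value of −148 e at pH 8 additionally
reflects titration conventions that are deliberately *not* modelled:
charge is always computed from an explicit scheme, never hard-coded).
Charge fractions f = n₊/N and g = n₋/N feed the polymer theory; the
simulation charge scheme (Arg/Lys +1, Asp/Glu −1, His +0.5) is kept
separate and used only by the coarse-grained model.

## Solution electrostatics

Bjerrum length l_B = e²/(4πε₀ε_r k_BT) from CODATA constants; water
permittivity from a standard empirical polynomial (ε_r(25 °C) ≈ 78.4),
overridable.  Debye length λ_D = (8π l_B N_A I)^{−1/2}; I ≤ 0 is an error
because the screening theory diverges there, and all analyses keep a
buffer floor of ~5 mM ionic strength (half-ionized 10 mM Tris), at which
λ_D ≈ 43 Å — below the protein scale, keeping the theory applicable.

Salt activities default to the Davies mean ionic activity,
log₁₀γ± = −A z₊|z₋|(√I/(1+√I) − 0.3 I), with A computed from temperature
(≈ 0.509 at 25 °C).  Davies is parameter-free and standard to I ≈ 0.5 M;
beyond that the result carries a `beyond_validity` flag instead of
failing.  A per-salt γ± table can be supplied to reproduce any other
activity convention; whether "activity" means the mean ionic activity or
the cation activity alone is a convention choice the caller controls by
supplying that table — the default is the mean ionic activity of the salt.

ΔG° = RT ln(K_d/1 M) with R = 1.9872 cal mol⁻¹ K⁻¹; standard state fixed
at 1 M.

## Binding isotherm fitting

Rh(a) = R₀(1 + ρ a/(K_d + a)) is fitted by weighted least squares
(weights 1/σ², unweighted fallback), with log₁₀K_d as the internal fit
variable for positivity and conditioning.  Initial guesses are
data-driven (R₀ = max Rh, R_min = min Rh, K_d at the midpoint crossing),
which removes starting-point sensitivity.  Standard errors come from the
linearised covariance; R_min = R₀(1+ρ) uses the delta method including
the ρ–R₀ covariance.  Residual-sign randomness in activity order is
tested with the exact Wald–Wolfowitz runs distribution (combinatorial
null for n ≤ 30, normal approximation beyond; zero residuals dropped; the
two-sided p doubles the smaller tail and is verified super-uniform).

## Polyampholyte theory

The effective excluded volume is read as
ν* = ν + (π l_B³/b³)[4(f−g)²(λ_D/l_B)² − (f+g)²(λ_D/l_B)] — the unique
dimensionally consistent parenthesisation, with the repulsive
(polyelectrolyte, ∝ l_B λ_D²) and attractive (polyampholyte, ∝ l_B² λ_D)
terms reported separately.  The expansion factor solves
α⁵ − α³ = (6N/π³)^{1/2}ν* by bracketed Brent iteration (residual < 1e−9);
for ν* below the minimum of α⁵−α³ the mean-field equation has no root
(collapse regime) and the solver reports breakdown rather than a
spurious root.  The α³-omitted closed form α = [(6N/π³)^{1/2}ν*]^{1/5} is
provided as a documented approximation: a direct scan shows a ~5–6%
error at α ≈ 2, shrinking as α grows.

Defaults for the AGARP-like chain: N = 506, b = 3.8 Å (Cα spacing),
binary f, g.  The Rg→Rh conversion uses the disordered-ensemble
correlation of Nygaard, Kragelund & Lindorff-Larsen (Biophys. J. 2017)
with a₁ = 0.216 Å⁻¹, a₂ = 4.06 Å, a₃ = 0.821 (transcribed constants,
overridable).  Two consequences of the functional form worth knowing:
Rh(I) is monotone decreasing only in the screening-dominated regime
(≲ 0.5 M for this chain); at multi-molar I the attractive term dies
faster than the repulsive one and the chain re-expands slightly, reaching
the bare-ν size only in the true λ_D → 0 limit.

The single parameter ν is fitted by Levenberg–Marquardt on weighted
residuals; the fit requires ≥ 3 points spanning ≥ 1 decade of I.

## Self-avoiding-walk ensemble (perfect-screening reference)

The reference state is a freely jointed chain of fixed 3.8 Å bonds with a
hard-core exclusion of 3.8 Å between all non-bonded beads.  Sampling uses
the **pivot algorithm**: a uniformly random rotation applied to the
sub-chain beyond a uniformly chosen bead, accepted iff no hard-core
violation.  The proposal is symmetric, so Metropolis
acceptance/rejection leaves the uniform SAW measure invariant; only
cross-half pair distances need checking.  Naive growth with
restart-on-collision is exactly uniform too but its survival probability
decays like ~0.7^N — astronomically small at N = 506 — so it is used only
as the small-N distributional oracle in the tests (the two samplers agree
at N = 10).  Defaults: burn-in max(1000, 5N) attempts from a straight
chain, thinning 20 attempts (acceptance ≈ 0.4 at N = 506); ensemble-level
runs use longer burn-in (≥ 30 000 attempts) as in the analysis scripts.

Measured with high statistics (1200 conformers per N), the *effective*
scaling exponent of mean Rg over N ∈ {64, …, 506} is 0.610 ± 0.006 —
above the asymptotic self-avoiding value 0.588, as expected from
finite-chain corrections for a maximally excluded chain (exclusion =
bond).  Mean Rg at N = 506 is ≈ 75 Å with per-conformer fluctuations of
~20% (CV > 0.15), so only long averages are meaningful.

## Coarse-grained HPS dynamics

One bead per residue; Ashbaugh–Hatch pair potential — full LJ shifted up
by (1−λ)ε inside its minimum, λ-scaled LJ outside — with per-residue σ
and hydrophobicity λ transcribed from the HPS parameterisation (Dignon
et al. 2018), ε = 0.2 kcal/mol, arithmetic-mean combination; plus
Debye–Hückel electrostatics q_iq_j(l_B/r)e^{−r/λ_D}RT.  Cutoffs (LJ 25 Å,
electrostatics 35 Å, both shifted to zero) are reproduction choices; the
temperature refinement of λ is exposed as per-residue linear coefficients
defaulting to zero, overridable with any published parameterisation.
Bonds are harmonic (k = 10 kJ mol⁻¹ Å⁻², r₀ = 3.8 Å).

Integration is overdamped Euler–Maruyama with free-draining per-bead
diffusion D = k_BT/(6πηa): Δx = (D/k_BT)F Δt + √(2DΔt)ξ.  The timestep is
validated against the bond relaxation time; starting structures are
relaxed by capped steepest descent (0.1 Å/step) before dynamics; blow-ups
(non-finite forces or per-step drifts beyond one bond length) abort with
diagnostics.  The integrator is validated against free-bead diffusion and
the exact bond Boltzmann distribution of a harmonic dimer.

Desk-scale runs cannot equilibrate the 506-mer (Rouse time ~ N²), so the
production-scale observable is deliberately reduced: simulations here use
short chains (N ≈ 30–64) and assert only the screening physics — smaller
equilibrium Rg at 100 mM than at ~0 ionic strength — not converged
506-mer averages.  Time-series analysis provides cumulative means and an
autocorrelation-aware standard error (integrated autocorrelation time
with Sokal's automatic window, cross-checked against Flyvbjerg–Petersen
blocking).

## Bead-model hydrodynamics

Mobilities are Rotne–Prager–Yamakawa with the overlap-corrected tensors
(positive definite for all configurations — mandatory here because the
3.8 Å bond is shorter than two bead diameters for most radius choices).
Units are chosen so 6πη = 1: every radius is pure geometry.

* **Kirkwood**: 1/Rh = (1/N²)[Σ_{i≠j}1/r_ij + Σ_i 1/a_i]; an upper bound
  on the diffusion coefficient, hence a lower bound on Rh.  (The RPY
  finite-size terms cancel exactly in the orientational trace, so the
  Oseen-style 1/r sum is exact for this bound.)
* **Rigid body**: friction from Cholesky solves of the 3N×3N mobility
  matrix against rigid velocity fields; rotational coupling off by
  default, available as a flag.
* **MDA (ensemble)**: per conformer, the minimum-dissipation friction
  over rigid motions — translation with freely relaxing rotation, i.e.
  the rotation-coupling-corrected friction; the *mobility* (1/3)tr μ is
  then averaged over the ensemble and inverted, making the ensemble Rh a
  harmonic mean of per-conformer radii.

The default monomer hydrodynamic radius is a_h = 1.9 Å — the steric
radius of the Cα chain (half the bond length), i.e. the hydrodynamic
bead equals the excluded-volume bead.  For open coils Rh depends only
weakly on a_h (the inter-bead double sum dominates), so this choice
matters at the ~1 Å level; with it the MDA radius of the 506-bead SAW
ensemble is 53–54 Å, matching the perfect-screening reference value,
while Kirkwood gives ~50 Å and the plain rigid-body mean ~57–58 Å.  The
estimator ordering Kirkwood ≤ MDA ≤ rigid holds conformer by conformer,
and the spread is largest (~15%) for dense space-filling clusters where
the Kirkwood bound is weakest.

## Observation models

FCS: G(τ) = (1/n)[1 + (T/(1−T))e^{−τ/τ_T}]Σ_i f_i(1+τ/τ_i)^{−1}
(1+τ/(s²τ_i))^{−1/2}; the triplet time is fixed at 2.4 μs (dye-conjugate
average), the structure parameter s is shared across curves and treated
as a calibration input (as is the beam waist), the free-dye component is
enabled by fixing its diffusion time from calibration.  Conversion:
D = w²/(4τ_D), Rh = k_BT/(6πηD); note that at fixed τ_D the inferred Rh
scales as 1/η.  Synthetic noise is multiplicative Gaussian with
σ(τ) ∝ G(τ)+floor — a pragmatic stand-in for photon statistics.

Droplet titrations: volume evolves by solvent-only evaporation and
logged stock aliquots; solute amount only by aliquots; concentration =
amount/volume, with mass conservation tested to 1e−12.  Solution
viscosities come from user-supplied per-salt tables (linear
interpolation); with no table the buffer value is used and flagged.

SEC: log(Rh) linear in elution volume, fitted to ≥ 3 standards; inverse
prediction carries the standard regression prediction interval
(propagated through the exponential) and extrapolation beyond the
standard range is flagged, never silent.

## Synthetic data and what the tests show

Every generator is a pure function of (truth, seed); every fitter has a
closed-loop recovery test (binding parameters, ν, τ_D, SEC).  The
generators reproduce the *statistical structure* each stage assumes —
sigmoidal titrations with Gaussian noise, model-exact FCS curves with
amplitude-proportional noise, i.i.d. charge placement — not instrument
raw data, optical artefacts, aggregation spikes, or sequence correlations
of real proteins.  Passing tests therefore demonstrate correctness of the
estimators under their own assumptions and the internal consistency of
the pipeline; they do not re-establish the experimental titration curves,
which require the deposited instrument data (the ν ≈ 2.42 integration
check runs only when a local copy of that data is present).

## Known limitations

* The Higgs–Joanny mean-field theory breaks down at very low ionic
  strength (λ_D beyond the chain size) and for strongly negative ν*;
  both regimes are reported as errors, not extrapolated.
* The rigid-body/MDA estimators treat each conformer as instantaneously
  rigid; fully flexible dynamics would sit between the Kirkwood and
  rigid bounds.
* Overdamped dynamics has no hydrodynamic interactions between beads;
  it is used for equilibrium sampling and qualitative screening trends,
  not for kinetics.
* Divalent-ion chelation — the mechanism behind the enhanced divalent
  compaction — is deliberately outside the model: the theory module
  captures Debye–Hückel screening only, which is exactly what makes the
  divalent deviation diagnosable.
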