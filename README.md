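# idpcollapse

Analysis toolkit for **counterion-driven compaction of highly charged
intrinsically disordered proteins** (IDPs).  The motivating system is an
aspartic/glutamic acid-rich coral protein (AGARP-like: 506 residues, net
charge near −148 e, linear charge density ≈ −0.3 e/residue) whose
hydrodynamic radius drops by ~40% as salt is titrated in — at far lower
activities for divalent cations (Ca²⁺, Mg²⁺) than monovalent ones
(Na⁺, K⁺).  The package implements every quantitative step of that
analysis so the full pipeline runs on synthetic data, end to end, with no
external downloads.

## What it computes

**Apparent binding isotherm.**  Rh versus salt activity *a* follows a
two-state model with identical, non-interacting sites:

    Rh(a) = R₀ (1 + ρ a / (K_d + a))

fitted by weighted nonlinear least squares (`isotherm`), giving K_d, ρ, R₀,
the saturation radius R_min = R₀(1+ρ), ΔG° = RT ln K_d, and a
Wald–Wolfowitz runs test (exact null for n ≤ 30) on residual signs.

**Polyampholyte screening theory.**  For a chain of N monomers, Kuhn
length b, charged fractions f (+) and g (−), screened electrostatics
renormalise the excluded volume (`polytheory`):

    ν* = ν + (π l_B³/b³) [4 (f−g)² (λ_D/l_B)² − (f+g)² (λ_D/l_B)]
    α⁵ − α³ = (6N/π³)^{1/2} ν*,   R_g = α b √(N/6)

with l_B the Bjerrum length, λ_D = (8π l_B N_A I)^{−1/2} the Debye length
(`solution`), and R_g → R_h through the empirical disordered-ensemble
conversion of Nygaard et al.  The single free parameter ν is fitted to
Rh(I) data.

**Conformer ensembles and hydrodynamics.**  `ensembles` samples
self-avoiding freely jointed chains (pivot algorithm; the perfect-screening
reference state) and runs desk-scale Brownian dynamics of the
coarse-grained HPS chain (hydrophobicity-scaled Lennard-Jones + Debye–Hückel
electrostatics).  `hydro` turns conformers into hydrodynamic radii via
Rotne–Prager–Yamakawa bead models: the Kirkwood double-sum bound, rigid-body
friction, and the minimum-dissipation approximation (MDA) averaged over the
ensemble.

**Observation models.**  `instruments` provides the FCS autocorrelation
model (two diffusing components + triplet), global curve fitting,
diffusion-time → Rh conversion, droplet-evaporation bookkeeping for
titrations, and log-linear SEC calibration with prediction uncertainty.
`seqcharge` handles sequence charge bookkeeping and acidic-run motif
scanning; `synthgen` generates seedable synthetic data for every stage.

## Worked example

```python
import numpy as np
from idpcollapse.synthgen import synth_titration
from idpcollapse.isotherm import fit_binding

curve, truth = synth_titration(Kd=2e-3, rho=-0.4, R0=80.0, sigma=1.5, seed=5)
fit = fit_binding(curve)
print(f"Kd   = {1e3*fit.Kd:.2f} ± {1e3*fit.Kd_stderr:.2f} mM")
print(f"rho  = {fit.rho:.3f} ± {fit.rho_stderr:.3f}")
print(f"R0   = {fit.R0:.1f} ± {fit.R0_stderr:.1f} A")
print(f"Rmin = {fit.Rmin:.1f} A,  dG0 = {fit.dG0:.2f} kcal/mol")
print(f"runs-test p = {fit.runs_test_p:.2f}")
```

prints

```
Kd   = 2.08 ± 0.32 mM
rho  = -0.393 ± 0.010
R0   = 79.5 ± 0.8 A
Rmin = 48.3 A,  dG0 = -3.66 kcal/mol
runs-test p = 0.35
```

i.e. the fit recovers the generating truth (K_d = 2 mM, ρ = −0.4,
R₀ = 80 Å) within its standard errors, the saturation radius lands near the
true 48 Å, a millimolar K_d maps to ≈ −3.7 kcal/mol — the solvent-exposed
salt-bridge energy scale — and the runs test finds no systematic misfit.

The numbered drivers under `analysis/` run the full story and write tables
to `results/`:

1. `01_sequence_charge.py` — charge composition and acidic-run census;
2. `02_isotherm_fits.py` — binding-parameter table for four salts;
3. `03_screening_theory.py` — predicted Rh(I) and the closed-loop ν fit;
4. `04_saw_hydro.py` — self-avoiding-walk ensemble, Rg/Rh estimators, and
   the deviation from the empirical R_g→R_h curve;
5. `05_langevin_screening.py` — coarse-grained dynamics at low vs high salt;
6. `06_instruments.py` — FCS global fit, droplet ledger, SEC calibration.

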