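"""Conformer-ensemble generation.

Two generators with very different physics:

* :func:`generate_saw_ensemble` — equilibrium sampling of a freely jointed
  hard-sphere chain (self-avoiding walk, fixed bond length, steric
  exclusion between non-bonded beads).  This is the perfect-screening
  reference state of a polyelectrolyte: all electrostatics switched off,
  only connectivity and excluded volume remain.  Sampling uses the pivot
  algorithm, a symmetric Metropolis chain over the uniform SAW measure.

* :func:`run_langevin` — desk-scale Brownian (overdamped Langevin)
  dynamics of the one-bead-per-residue HPS chain: harmonic bonds,
  Ashbaugh–Hatch hydrophobicity-scaled Lennard-Jones interactions and
  Debye–Hueckel screened electrostatics, both truncated and shifted.
  It emits an Rg time series with cumulative averages and thinned
  conformers.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import hps_data
from .seqcharge import ProteinSequence
from .solution import SolutionConditions

DEFAULT_BOND = 3.8  # A, C-alpha spacing
DEFAULT_BEAD_RADIUS = 1.9  # A, monomer hydrodynamic radius (see hydro docs)


@dataclass
class ConformerEnsemble:
    """A set of bead-chain conformers with hydrodynamic bead radii."""

    conformers: list[np.ndarray]  # each (N, 3), Angstrom
    bond_length: float
    source: str  # "SAW" | "Langevin" | "file"
    seed: int | None = None
    bead_radius: float = DEFAULT_BEAD_RADIUS  # A, uniform

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        shapes = {c.shape for c in self.conformers}
        if len(shapes) != 1 or next(iter(shapes))[1] != 3:
            raise ValueError("all conformers must share one (N, 3) shape")
        if self.bead_radius <= 0:
            raise ValueError("bead radius must be positive")

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def n_beads(self) -> int:
        return self.conformers[0].shape[0]

    def to_xyz(self, path: str | Path, element: str = "C") -> None:
        """Write all conformers as a concatenated XYZ trajectory."""
        with open(path, "w") as fh:
            for i, c in enumerate(self.conformers):
                fh.write(f"{c.shape[0]}\n")
                fh.write(f"{self.source} conformer {i}\n")
                for x, y, z in c:
                    fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")

    def to_pdb(self, path: str | Path, conformer: int = 0) -> None:
        """Write one conformer as a minimal single-chain C-alpha PDB."""
        c = self.conformers[conformer]
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(c, start=1):
                fh.write(
                    f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("END\n")

    @classmethod
    def from_xyz(
        cls, path: str | Path, bond_length: float = DEFAULT_BOND,
        bead_radius: float = DEFAULT_BEAD_RADIUS,
    ) -> "ConformerEnsemble":
        """Read a concatenated XYZ trajectory written by :meth:`to_xyz`."""
        conformers = []
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            block = lines[i + 2 : i + 2 + n]
            coords = np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in block]
            )
            conformers.append(coords)
            i += 2 + n
        return cls(conformers, bond_length, "file", bead_radius=bead_radius)


# --------------------------------------------------------------------------
# Self-avoiding walk (pivot sampling)
# --------------------------------------------------------------------------

def _straight_chain(n: int, bond: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = bond * np.arange(n)
    return coords


def _pivot_once(
    coords: np.ndarray, exclusion: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One pivot attempt: rotate the tail beyond a random bead by a uniform
    random rotation; accept iff no non-bonded pair comes closer than the
    exclusion distance.  Distances within each rigid half are preserved, so
    only cross-half pairs need checking."""
    n = coords.shape[0]
    if n < 3:
        # a dimer has no non-bonded pairs; any rotation is valid
        k = 0
    else:
        k = int(rng.integers(1, n - 1))
    rot = Rotation.random(rng=rng).as_matrix()
    head = coords[: k + 1]
    tail = coords[k + 1 :]
    new_tail = (tail - coords[k]) @ rot.T + coords[k]
    if n >= 3 and head.shape[0] >= 1 and new_tail.shape[0] >= 1:
        d = cdist(head, new_tail)
        # bead k and k+1 are bonded; every other cross pair is non-bonded
        d[k, 0] = np.inf
        if d.min() < exclusion:
            return coords, False
    out = coords.copy()
    out[k + 1 :] = new_tail
    return out, True


def saw_is_valid(coords: np.ndarray, bond: float, exclusion: float,
                 tol: float = 1e-9) -> bool:
    """Check the hard constraints: exact bond lengths, no non-bonded pair
    closer than the exclusion distance."""
    bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(np.abs(bonds - bond) > tol * bond):
        return False
    n = coords.shape[0]
    if n < 3:
        return True
    d = cdist(coords, coords)
    iu = np.triu_indices(n, k=2)
    return bool(d[iu].min() >= exclusion * (1 - tol))


def generate_saw_ensemble(
    N: int,
    bond: float = DEFAULT_BOND,
    exclusion: float = DEFAULT_BOND,
    n_conf: int = 100,
    seed: int = 0,
    burn_in: int | None = None,
    thin: int | None = None,
    min_acceptance: float = 0.02,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> ConformerEnsemble:
    """Sample self-avoiding freely jointed chains by the pivot algorithm.

    The chain has ``N`` beads, fixed bond length ``bond`` and a hard-core
    exclusion ``exclusion`` between all non-bonded beads.  Pivot moves
    (uniform random rotation of the sub-chain beyond a uniformly chosen
    bead) form a symmetric proposal, so plain Metropolis
    acceptance/rejection leaves the uniform SAW measure invariant; samples
    are taken after ``burn_in`` attempts, every ``thin`` attempts.

    Naive chain-growth with restart-on-collision is exact too, but its
    survival probability decays exponentially in ``N`` and is astronomically
    small at N ~ 500; the pivot chain delivers the same distribution at
    usable cost.

    Defaults: ``burn_in = max(1000, 5 N)`` attempts, ``thin = 20``.

    Raises if ``exclusion > bond`` (no such walk exists) or if the pivot
    acceptance rate falls below ``min_acceptance`` (pathological exclusion).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if exclusion > bond:
        raise ValueError(
            "exclusion must not exceed the bond length "
            "(consecutive beads would violate the hard core)"
        )
    if n_conf < 1:
        raise ValueError("n_conf must be >= 1")
    if burn_in is None:
        burn_in = max(1000, 5 * N)
    if thin is None:
        thin = 20
    rng = np.random.default_rng(seed)
    coords = _straight_chain(N, bond)
    accepted = attempted = 0
    conformers: list[np.ndarray] = []
    while len(conformers) < n_conf:
        coords, ok = _pivot_once(coords, exclusion, rng)
        attempted += 1
        accepted += ok
        if attempted > burn_in and (attempted - burn_in) % thin == 0:
            conformers.append(coords.copy())
        if attempted >= 500 and accepted / attempted < min_acceptance:
            raise RuntimeError(
                f"pivot acceptance {accepted/attempted:.3f} below "
                f"{min_acceptance}; reduce the exclusion distance"
            )
    return ConformerEnsemble(
        conformers, bond, "SAW", seed=seed, bead_radius=bead_radius
    )


def radius_of_gyration_series(ensemble: ConformerEnsemble) -> np.ndarray:
    """Rg of every conformer (convenience wrapper around hydro)."""
    from .hydro import radius_of_gyration

    return np.array([radius_of_gyration(c) for c in ensemble.conformers])


# --------------------------------------------------------------------------
# Coarse-grained HPS chain and Brownian dynamics
# --------------------------------------------------------------------------

@dataclass
class HPSParameters:
    """Pairwise interaction parameters of the HPS chain.

    ``sigma`` and ``lam`` are per-bead arrays; pair values use arithmetic
    means.  ``lambda_dT`` applies a linear temperature refinement
    lambda_i(T) = lambda_i + d lambda_i/dT (T - 298.15 K), clipped to
    [0, 1]; the default coefficients are zero.
    """

    sigma: np.ndarray  # (N,), A
    lam: np.ndarray  # (N,), [0, 1]
    charge: np.ndarray  # (N,), e
    epsilon: float = hps_data.HPS_EPSILON  # kcal/mol
    bond_k: float = hps_data.HPS_BOND_K  # kcal/(mol A^2)
    bond_r0: float = hps_data.HPS_BOND_R0  # A
    lj_cutoff: float = hps_data.DEFAULT_LJ_CUTOFF  # A
    elec_cutoff: float = hps_data.DEFAULT_ELEC_CUTOFF  # A
    lambda_dT: np.ndarray | None = None  # (N,), 1/K

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        if self.epsilon <= 0 or np.any(self.sigma <= 0):
            raise ValueError("epsilon and sigma must be positive")
        if np.any((self.lam < 0) | (self.lam > 1)):
            raise ValueError("lambda values must lie in [0, 1]")

    @classmethod
    def from_sequence(cls, seq: ProteinSequence | str, **kw) -> "HPSParameters":
        if isinstance(seq, str):
            seq = ProteinSequence("anonymous", seq)
        sig = np.array([hps_data.HPS_SIGMA_LAMBDA[aa][0] for aa in seq])
        lam = np.array([hps_data.HPS_SIGMA_LAMBDA[aa][1] for aa in seq])
        q = np.array([hps_data.HPS_CHARGE.get(aa, 0.0) for aa in seq])
        return cls(sigma=sig, lam=lam, charge=q, **kw)

    def lam_at(self, T: float) -> np.ndarray:
        if self.lambda_dT is None:
            return self.lam
        return np.clip(self.lam + self.lambda_dT * (T - 298.15), 0.0, 1.0)

    @property
    def n_beads(self) -> int:
        return int(self.sigma.size)


def hps_pair_potential(
    r: "float | np.ndarray",
    sigma_ij: float,
    lambda_ij: float,
    q_ij: float,
    params: HPSParameters,
    conditions: SolutionConditions,
) -> "float | np.ndarray":
    """Pair energy (kcal/mol) of the HPS model at separation ``r``.

    Ashbaugh–Hatch form: inside the LJ minimum (r <= 2^(1/6) sigma) the full
    LJ potential shifted up by (1 - lambda) eps; outside, LJ scaled by
    lambda.  Screened Coulomb q_i q_j (l_B / r) exp(-r/lambda_D) RT on top.
    Each part is truncated and shifted to zero at its cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    eps = params.epsilon

    def lj(x):
        sr6 = (sigma_ij / x) ** 6
        return 4.0 * eps * (sr6**2 - sr6)

    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    ah = np.where(r <= rmin, lj(r) + (1.0 - lambda_ij) * eps, lambda_ij * lj(r))
    shift = lambda_ij * lj(params.lj_cutoff)
    ah = np.where(r < params.lj_cutoff, ah - shift, 0.0)

    kT = conditions.kT_kcal
    lB, lD = conditions.bjerrum, conditions.debye
    dh = q_ij * kT * lB * np.exp(-r / lD) / r
    dh_shift = q_ij * kT * lB * math.exp(-params.elec_cutoff / lD) / params.elec_cutoff
    dh = np.where(r < params.elec_cutoff, dh - dh_shift, 0.0)
    out = ah + dh
    return float(out) if out.ndim == 0 else out


def _forces(
    coords: np.ndarray,
    params: HPSParameters,
    conditions: SolutionConditions,
    lam: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Total force (kcal/mol/A) on every bead and the potential energy."""
    n = coords.shape[0]
    eps = params.epsilon
    kT = conditions.kT_kcal
    lB, lD = conditions.bjerrum, conditions.debye

    dr = coords[:, None, :] - coords[None, :, :]  # (n, n, 3), i - j
    dist = np.sqrt(np.einsum("ijk,ijk->ij", dr, dr))
    np.fill_diagonal(dist, np.inf)

    sig = 0.5 * (params.sigma[:, None] + params.sigma[None, :])
    lmb = 0.5 * (lam[:, None] + lam[None, :])
    qq = params.charge[:, None] * params.charge[None, :]

    # exclude bonded neighbours from non-bonded terms
    bonded = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    bonded[idx, idx + 1] = bonded[idx + 1, idx] = True
    nb = ~bonded
    np.fill_diagonal(nb, False)

    with np.errstate(over="ignore", invalid="ignore"):
        sr6 = (sig / dist) ** 6
        sr12 = sr6 * sr6
        # dU_LJ/dr = 4 eps (-12 sr12 + 6 sr6)/r ; force magnitude = -dU/dr
        flj = 24.0 * eps * (2.0 * sr12 - sr6) / dist  # repulsive positive
        rmin = 2.0 ** (1.0 / 6.0) * sig
        scale = np.where(dist <= rmin, 1.0, lmb)
        f_ah = flj * scale
        f_ah = np.where((dist < params.lj_cutoff) & nb, f_ah, 0.0)
        u_lj = 4.0 * eps * (sr12 - sr6)
        u_ah = np.where(dist <= rmin, u_lj + (1.0 - lmb) * eps, lmb * u_lj)
        shift = lmb * 4.0 * eps * ((sig / params.lj_cutoff) ** 12
                                   - (sig / params.lj_cutoff) ** 6)
        u_ah = np.where((dist < params.lj_cutoff) & nb, u_ah - shift, 0.0)

        u_dh_raw = qq * kT * lB * np.exp(-dist / lD) / dist
        f_dh = u_dh_raw * (1.0 / dist + 1.0 / lD)  # -dU/dr, radial outward
        elec_mask = (dist < params.elec_cutoff) & nb
        f_dh = np.where(elec_mask, f_dh, 0.0)
        dh_shift = qq * kT * lB * math.exp(-params.elec_cutoff / lD) \
            / params.elec_cutoff
        u_dh = np.where(elec_mask, u_dh_raw - dh_shift, 0.0)

    fmag = f_ah + f_dh  # dU/dr with sign: positive => repulsion along +r_ij
    with np.errstate(invalid="ignore"):
        fvec = (fmag / dist)[:, :, None] * dr
    fvec = np.nan_to_num(fvec)
    force = fvec.sum(axis=1)

    # bonds
    bvec = coords[1:] - coords[:-1]
    blen = np.linalg.norm(bvec, axis=1)
    fb = -params.bond_k * (blen - params.bond_r0)  # along bond direction
    fdir = bvec / blen[:, None]
    force[:-1] -= fb[:, None] * fdir
    force[1:] += fb[:, None] * fdir
    u_bond = 0.5 * params.bond_k * np.sum((blen - params.bond_r0) ** 2)
    energy = 0.5 * (u_ah.sum() + u_dh.sum()) + u_bond
    return force, float(energy)


@dataclass
class LangevinTrajectory:
    """Output of a Brownian-dynamics run."""

    times: np.ndarray  # ps, at sample points
    rg: np.ndarray  # A, instantaneous at sample points
    energies: np.ndarray  # kcal/mol
    conformers: list[np.ndarray]  # thinned snapshots
    seed: int
    dt: float  # ps
    n_steps: int
    parameters: HPSParameters | None = None

    @property
    def cumulative_mean_rg(self) -> np.ndarray:
        return np.cumsum(self.rg) / np.arange(1, self.rg.size + 1)


def run_langevin(
    seq: ProteinSequence | str | None,
    conditions: SolutionConditions,
    n_steps: int,
    dt: float = 0.1,  # ps
    seed: int = 0,
    params: HPSParameters | None = None,
    sample_every: int = 100,
    conformer_every: int | None = None,
    initial: np.ndarray | None = None,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    interactions: bool = True,
    minimize_steps: int = 200,
) -> LangevinTrajectory:
    """Overdamped (Brownian) Langevin dynamics of the HPS chain.

    Euler–Maruyama integration of dx = (D/kT) F dt + sqrt(2 D dt) xi with a
    free-draining per-bead diffusion coefficient D = kT / (6 pi eta a).
    Times are in ps, lengths in Angstrom, energies in kcal/mol.

    ``interactions=False`` switches off all conservative forces (free
    diffusion; used for validating the integrator).  The timestep is checked
    against the bond relaxation time; a blow-up (non-finite coordinates or a
    step larger than one bond length) aborts with diagnostics.
    """
    if params is None:
        if seq is None:
            raise ValueError("provide a sequence or explicit HPSParameters")
        params = HPSParameters.from_sequence(seq)
    n = params.n_beads
    rng = np.random.default_rng(seed)

    kT = conditions.kT_kcal  # kcal/mol
    # D = kB T / (6 pi eta a): SI, then m^2/s -> A^2/ps (x 1e8)
    from scipy import constants as _c

    D = (
        _c.k * conditions.temperature
        / (6.0 * math.pi * conditions.viscosity * 1e-3 * bead_radius * 1e-10)
    ) * 1e8  # A^2/ps
    if interactions:
        tau_bond = kT / (D * 2.0 * params.bond_k)  # bond relaxation, ps
        if dt > tau_bond:
            raise ValueError(
                f"dt={dt} ps exceeds the bond relaxation time {tau_bond:.3g} ps"
            )

    if initial is not None:
        coords = np.array(initial, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError("initial coordinates must be (N, 3)")
    elif n == 1:
        coords = np.zeros((1, 3))
    else:
        # mild SAW start to avoid initial overlaps
        coords = generate_saw_ensemble(
            n, bond=params.bond_r0, exclusion=min(params.bond_r0, 3.8),
            n_conf=1, seed=seed, burn_in=max(200, 2 * n), thin=1,
        ).conformers[0]

    mob = D / kT  # A^2 / (ps kcal/mol)
    noise_sd = math.sqrt(2.0 * D * dt)
    lam = params.lam_at(conditions.temperature)

    # relax steric overlaps of the starting structure (capped steepest
    # descent) so the first dynamics steps are inside the stability region
    if interactions and n > 1 and minimize_steps > 0:
        cap = 0.1  # A per bead per relaxation step
        for _ in range(minimize_steps):
            force, _ = _forces(coords, params, conditions, lam)
            step_vec = mob * force * dt
            scale = np.minimum(1.0, cap / np.maximum(
                np.linalg.norm(step_vec, axis=1, keepdims=True), 1e-12))
            coords = coords + step_vec * scale

    times, rgs, energies, snapshots = [], [], [], []
    if conformer_every is None:
        conformer_every = max(sample_every * 10, n_steps // 50 or 1)
    centroid_rg = lambda c: float(
        np.sqrt(np.mean(np.sum((c - c.mean(axis=0)) ** 2, axis=1)))
    )
    for step in range(1, n_steps + 1):
        if interactions and n > 1:
            force, energy = _forces(coords, params, conditions, lam)
        else:
            force, energy = np.zeros_like(coords), 0.0
        disp = mob * force * dt
        max_disp = np.abs(disp).max() if disp.size else 0.0
        if not np.isfinite(max_disp) or max_disp > params.bond_r0:
            raise RuntimeError(
                f"energy blow-up at step {step}: max deterministic "
                f"displacement {max_disp:.3g} A (dt too large?)"
            )
        coords = coords + disp + noise_sd * rng.standard_normal(coords.shape)
        if step % sample_every == 0:
            times.append(step * dt)
            rgs.append(centroid_rg(coords))
            energies.append(energy)
        if step % conformer_every == 0:
            snapshots.append(coords.copy())
    return LangevinTrajectory(
        times=np.array(times),
        rg=np.array(rgs),
        energies=np.array(energies),
        conformers=snapshots or [coords.copy()],
        seed=seed,
        dt=dt,
        n_steps=n_steps,
        parameters=params,
    )


# --------------------------------------------------------------------------
# Time-series analysis
# --------------------------------------------------------------------------

def blocking_analysis(series: np.ndarray, min_blocks: int = 16) -> np.ndarray:
    """Flyvbjerg–Petersen blocking: naive stderr of the mean at successive
    block-halving levels (levels with fewer than ``min_blocks`` blocks are
    dropped).  Returns an array of stderr estimates, level 0 first."""
    x = np.asarray(series, dtype=float)
    out = []
    while x.size >= min_blocks:
        out.append(np.std(x, ddof=1) / math.sqrt(x.size))
        if x.size % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    return np.array(out)


def stationary_stderr(series: np.ndarray) -> float:
    """Autocorrelation-aware stderr of the mean of a stationary series.

    Uses the integrated autocorrelation time with Sokal's automatic window
    (window W is the smallest lag with W >= 5 tau_int); reduces to the naive
    sigma/sqrt(n) for white noise.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    x = x - x.mean()
    var = float(np.mean(x**2))
    if var == 0.0:
        return 0.0
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    for w in range(1, n):
        tau = 1.0 + 2.0 * float(rho[1 : w + 1].sum())
        if w >= 5.0 * tau:
            break
    tau = max(tau, 1.0)
    return math.sqrt(var * tau / n)


def rg_timeseries(
    traj: "LangevinTrajectory | np.ndarray",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Instantaneous Rg series, cumulative mean, and an autocorrelation-aware
    stderr of the long-time average (Sokal-window estimate cross-checked by
    the blocking table from :func:`blocking_analysis`)."""
    rg = traj.rg if isinstance(traj, LangevinTrajectory) else np.asarray(traj)
    if rg.size < 2:
        raise ValueError("need at least 2 samples")
    cum = np.cumsum(rg) / np.arange(1, rg.size + 1)
    return rg, cum, stationary_stderr(rg)
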