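"""Conformer generation: SAW pivot sampling, HPS potential, Brownian dynamics."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from idpcollapse import ensembles as ens
from idpcollapse.ensembles import (
    ConformerEnsemble,
    HPSParameters,
    blocking_analysis,
    generate_saw_ensemble,
    hps_pair_potential,
    rg_timeseries,
    run_langevin,
    saw_is_valid,
    stationary_stderr,
)
from idpcollapse.hydro import radius_of_gyration
from idpcollapse.solution import SolutionConditions


def naive_saw_growth(N, bond, exclusion, n_chains, rng):
    """Brute-force simple sampling: grow a freely jointed chain step by
    step and restart the WHOLE chain on any hard-core violation.  Exactly
    uniform over SAWs, affordable only for small N; serves as the
    distributional oracle for the pivot sampler."""
    chains = []
    while len(chains) < n_chains:
        coords = np.zeros((N, 3))
        ok = True
        for i in range(1, N):
            v = rng.standard_normal(3)
            coords[i] = coords[i - 1] + bond * v / np.linalg.norm(v)
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - coords[i], axis=1)
                if d.min() < exclusion:
                    ok = False
                    break
        if ok:
            chains.append(coords)
    return chains


class TestSAWSampler:
    def test_hard_constraints_hold(self):
        e = generate_saw_ensemble(64, n_conf=20, seed=1)
        for c in e.conformers:
            assert saw_is_valid(c, 3.8, 3.8)

    def test_dimer_rg_degenerate(self):
        e = generate_saw_ensemble(2, bond=3.8, n_conf=5, seed=0)
        for c in e.conformers:
            assert radius_of_gyration(c) == pytest.approx(1.9, abs=1e-9)

    def test_seed_reproducibility(self):
        a = generate_saw_ensemble(32, n_conf=3, seed=7)
        b = generate_saw_ensemble(32, n_conf=3, seed=7)
        for x, y in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(x, y)

    def test_exclusion_larger_than_bond_rejected(self):
        with pytest.raises(ValueError):
            generate_saw_ensemble(10, bond=3.8, exclusion=4.0, n_conf=1, seed=0)

    def test_pivot_matches_naive_growth_oracle(self):
        """Mean Rg and mean end-to-end distance of the pivot ensemble agree
        with exact simple-sampling (restart-on-collision growth) at N = 10
        within combined 3 sigma."""
        N, bond = 10, 3.8
        rng = np.random.default_rng(123)
        oracle = naive_saw_growth(N, bond, bond, 800, rng)
        pivot = generate_saw_ensemble(N, n_conf=800, seed=4, thin=10).conformers

        def stats(chains):
            rg = np.array([radius_of_gyration(c) for c in chains])
            ee = np.array([np.linalg.norm(c[-1] - c[0]) for c in chains])
            return rg.mean(), rg.std() / math.sqrt(len(chains)), \
                ee.mean(), ee.std() / math.sqrt(len(chains))

        rg_o, se_o, ee_o, see_o = stats(oracle)
        rg_p, se_p, ee_p, see_p = stats(pivot)
        # pivot samples are thinned but still correlated; inflate allowance
        assert abs(rg_o - rg_p) < 3 * math.hypot(se_o, 3 * se_p)
        assert abs(ee_o - ee_p) < 3 * math.hypot(see_o, 3 * see_p)

    def test_direction_relabelling_invariance(self):
        """Rg is invariant under reversing the chain labelling."""
        e = generate_saw_ensemble(20, n_conf=10, seed=3)
        for c in e.conformers:
            assert radius_of_gyration(c[::-1]) == pytest.approx(
                radius_of_gyration(c)
            )

    def test_xyz_roundtrip(self, tmp_path):
        e = generate_saw_ensemble(12, n_conf=4, seed=5)
        p = tmp_path / "ens.xyz"
        e.to_xyz(p)
        back = ConformerEnsemble.from_xyz(p, bond_length=3.8)
        assert back.n_conformers == 4
        for a, b in zip(e.conformers, back.conformers):
            np.testing.assert_allclose(a, b, atol=1e-3)

    def test_pdb_export_readable_by_biotite(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        e = generate_saw_ensemble(8, n_conf=1, seed=5)
        p = tmp_path / "chain.pdb"
        e.to_pdb(p)
        structure = pdb.PDBFile.read(str(p)).get_structure(model=1)
        np.testing.assert_allclose(structure.coord, e.conformers[0], atol=1e-3)


class TestHPSPotential:
    @staticmethod
    def params():
        return HPSParameters.from_sequence("DEKGLS")

    @staticmethod
    def conds():
        return SolutionConditions(temperature=298.15, ionic_strength=0.1)

    def test_continuity_at_lj_minimum(self):
        p, c = self.params(), self.conds()
        sig, lam = 6.0, 0.7
        rmin = 2 ** (1 / 6) * sig
        below = hps_pair_potential(rmin - 1e-9, sig, lam, 0.0, p, c)
        above = hps_pair_potential(rmin + 1e-9, sig, lam, 0.0, p, c)
        assert below == pytest.approx(above, abs=1e-6)
        # both branches equal -lambda eps at the minimum (before cutoff shift)
        shift = lam * 4 * p.epsilon * ((sig / p.lj_cutoff) ** 12
                                       - (sig / p.lj_cutoff) ** 6)
        assert below == pytest.approx(-lam * p.epsilon - shift, abs=1e-9)

    def test_limiting_forms(self):
        p, c = self.params(), self.conds()
        r = np.linspace(3.0, 20.0, 200)
        # lambda = 1: plain truncated-shifted LJ
        full = hps_pair_potential(r, 6.0, 1.0, 0.0, p, c)
        sr6 = (6.0 / r) ** 6
        lj = 4 * p.epsilon * (sr6**2 - sr6)
        ljc = 4 * p.epsilon * ((6.0 / p.lj_cutoff) ** 12 - (6.0 / p.lj_cutoff) ** 6)
        np.testing.assert_allclose(full, lj - ljc, atol=1e-12)
        # lambda = 0: purely repulsive (WCA); nonnegative everywhere
        wca = hps_pair_potential(r, 6.0, 0.0, 0.0, p, c)
        assert np.all(wca >= -1e-12)

    def test_screened_coulomb_at_debye_length(self):
        p, c = self.params(), self.conds()
        u = hps_pair_potential(c.debye, 1e-6, 0.0, 1.0, p, c)
        expected = math.exp(-1) * (c.bjerrum / c.debye) * c.kT_kcal
        shift = c.kT_kcal * c.bjerrum * math.exp(-p.elec_cutoff / c.debye) \
            / p.elec_cutoff
        assert u == pytest.approx(expected - shift, rel=1e-6)

    def test_lambda_temperature_hook(self):
        p = HPSParameters.from_sequence("AAAA",
                                        lambda_dT=np.full(4, 1e-3))
        assert np.allclose(p.lam_at(298.15), p.lam)
        assert np.all(p.lam_at(308.15) >= p.lam)


class TestLangevin:
    def test_free_bead_diffusion(self):
        """A single non-interacting bead diffuses with variance 2 D t per
        axis; compare the empirical MSD of many short runs with the input
        diffusion coefficient."""
        cond = SolutionConditions(temperature=298.15, ionic_strength=0.1)
        p = HPSParameters(sigma=[5.0], lam=[0.5], charge=[0.0])
        from scipy import constants as sc

        a = 4.2
        D = (sc.k * 298.15 / (6 * math.pi * cond.viscosity * 1e-3 * a * 1e-10)) * 1e8
        n_rep, steps, dt = 200, 50, 0.5
        disp2 = []
        for seed in range(n_rep):
            t = run_langevin(None, cond, steps, dt=dt, seed=seed, params=p,
                            sample_every=steps, bead_radius=a,
                            interactions=False)
            disp2.append(np.sum(t.conformers[-1][0] ** 2))
        msd = np.mean(disp2)
        expected = 6 * D * steps * dt
        se = np.std(disp2) / math.sqrt(n_rep)
        assert abs(msd - expected) < 3 * se

    def test_harmonic_dimer_bond_boltzmann(self):
        """With non-bonded interactions off, the dimer bond length samples
        p(r) ~ r^2 exp(-k (r-r0)^2 / 2kT); compare mean and sd of r against
        numerical quadrature of the target density."""
        cond = SolutionConditions(temperature=298.15, ionic_strength=0.1)
        p = HPSParameters(sigma=[1e-3, 1e-3], lam=[0.0, 0.0],
                          charge=[0.0, 0.0])
        traj = run_langevin(
            None, cond, 120_000, dt=0.2, seed=9, params=p, sample_every=20,
            initial=np.array([[0.0, 0, 0], [3.8, 0, 0]]),
        )
        # bond lengths from sampled conformers are too sparse; recompute from
        # rg samples: for a dimer Rg = r/2
        r = 2 * traj.rg
        kT = cond.kT_kcal
        grid = np.linspace(1e-3, 12, 4000)
        w = grid**2 * np.exp(-p.bond_k * (grid - p.bond_r0) ** 2 / (2 * kT))
        w /= np.trapezoid(w, grid)
        mean_th = np.trapezoid(grid * w, grid)
        sd_th = math.sqrt(np.trapezoid((grid - mean_th) ** 2 * w, grid))
        se = stationary_stderr(r)
        assert abs(r.mean() - mean_th) < max(3 * se, 0.05)
        assert np.std(r) == pytest.approx(sd_th, rel=0.10)

    def test_charged_chain_compacts_at_high_ionic_strength(self):
        """A short acidic chain swells at micromolar ionic strength and
        compacts at 100 mM (screening), same seed protocol."""
        seq = "DE" * 15
        rgs = {}
        for I in (1e-6, 0.1):
            cond = SolutionConditions(temperature=298.15, ionic_strength=I)
            traj = run_langevin(seq, cond, 60_000, dt=0.1, seed=4,
                                sample_every=50)
            rgs[I] = traj.rg[len(traj.rg) // 2:].mean()
        assert rgs[1e-6] > rgs[0.1]

    def test_timestep_guard(self):
        cond = SolutionConditions(temperature=298.15, ionic_strength=0.1)
        with pytest.raises(ValueError, match="relaxation"):
            run_langevin("AAAA", cond, 10, dt=1e3, seed=0)

    def test_seed_reproducibility(self):
        cond = SolutionConditions(temperature=298.15, ionic_strength=0.1)
        t1 = run_langevin("DEKG", cond, 500, seed=3, sample_every=50)
        t2 = run_langevin("DEKG", cond, 500, seed=3, sample_every=50)
        np.testing.assert_array_equal(t1.rg, t2.rg)


class TestTimeSeries:
    def test_constant_series(self):
        rg, cum, se = rg_timeseries(np.full(100, 5.0))
        assert np.all(cum == 5.0)
        assert se == 0.0

    def test_white_noise_stderr(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8192)
        se = stationary_stderr(x)
        assert se == pytest.approx(1 / math.sqrt(8192), rel=0.10)
        blocks = blocking_analysis(x)
        assert blocks[0] == pytest.approx(se, rel=0.05)

    def test_ar1_stderr_matches_effective_sample_size(self):
        """AR(1) with phi = 0.9: stderr of the mean should match
        sd * sqrt((1+phi)/(1-phi)/n) within 20%."""
        phi, n = 0.9, 40_000
        rng = np.random.default_rng(7)
        e = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = e[0]
        for i in range(1, n):
            y[i] = phi * y[i - 1] + e[i]
        se = stationary_stderr(y)
        truth = np.std(y) * math.sqrt((1 + phi) / (1 - phi) / n)
        assert se == pytest.approx(truth, rel=0.20)
        # blocking plateau agrees with the windowed estimate
        assert blocking_analysis(y)[-3:].max() == pytest.approx(se, rel=0.35)

    def test_cumulative_mean_converges(self):
        cond = SolutionConditions(temperature=298.15, ionic_strength=0.1)
        traj = run_langevin("GSGSGSGS", cond, 5000, seed=1, sample_every=10)
        _, cum, _ = rg_timeseries(traj)
        assert np.isfinite(cum).all()
        assert abs(cum[-1] - traj.rg.mean()) < 1e-12
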