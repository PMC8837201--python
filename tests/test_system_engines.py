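"""Braid construction, BD integrator, and MC sampler correctness."""

import numpy as np
import pytest

from topobraid import (
    BraidSystem,
    Conformation,
    ForceFieldParams,
    UnitSystem,
    bd_step,
    build_initial_braid,
    count_crossings,
    mc_sweep,
    run_bd,
    run_mc,
)
from topobraid.mc import MCMoveSet
from topobraid.mechanics import wlc_relative_extension
from topobraid.system import BraidConstructionError, effective_sample_size
from topobraid.units import bond_rest_length, total_energy


class TestBuilder:
    def test_zero_turns_straight_chains(self, coarse_units, coarse_params):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=0)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        assert count_crossings(conf) == 0
        # both chains vertical above their anchors
        for c in range(2):
            xy = conf.chain(c)[:, :2]
            assert np.allclose(xy, xy[0], atol=1e-9)

    @pytest.mark.parametrize("n_turns", [1, -1, 2, -3, 5])
    def test_crossing_number_by_construction(self, coarse_units,
                                             coarse_params, n_turns):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=n_turns)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        assert count_crossings(conf) == n_turns

    def test_geometry_constraints(self, coarse_units, coarse_params):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=2)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        b = conf.bonds()
        rb = np.linalg.norm(
            conf.positions[b[:, 1]] - conf.positions[b[:, 0]], axis=1
        )
        assert rb.max() < 0.99 * coarse_params.r0
        # non-bonded separations above the overlap limit
        n = len(conf.positions)
        d = conf.positions[:, None] - conf.positions[None, :]
        r = np.sqrt((d**2).sum(-1))
        iu = np.triu_indices(n, k=2)
        assert r[iu].min() > 0.9

    def test_infeasible_turns_rejected(self, coarse_units, coarse_params):
        system = BraidSystem(dna_bp=300, spacing_e_nm=90, force_pN=1.0,
                             n_turns=40)
        with pytest.raises(BraidConstructionError):
            build_initial_braid(system, coarse_units, coarse_params)

    def test_energy_finite(self, coarse_units, coarse_params):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=-3)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        assert np.isfinite(total_energy(conf, coarse_params))

    def test_slack_start_preserves_topology(self, coarse_units,
                                            coarse_params):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=0.5,
                             n_turns=1)
        conf = build_initial_braid(system, coarse_units, coarse_params,
                                   extension_sigma=25.0)
        assert count_crossings(conf) == 1
        assert conf.anchor_top[0, 2] == pytest.approx(25.0, abs=8.0)


class TestBDStep:
    def test_zero_noise_at_equilibrium_stays(self, rng):
        pos = np.zeros((5, 3))
        new = bd_step(pos, np.zeros_like(pos), 0.01, 1.0, rng,
                      noise_scale=0.0)
        assert np.allclose(new, pos, atol=1e-12)

    def test_free_diffusion_msd(self):
        """MSD per axis = 2 (kT/gamma) t for a free bead."""
        rng = np.random.default_rng(42)
        n_walkers, n_steps, dt = 400, 1000, 0.01
        pos = np.zeros((n_walkers, 3))
        for _ in range(n_steps):
            pos = bd_step(pos, np.zeros_like(pos), dt, 1.0, rng)
        msd = np.mean(pos**2, axis=0)
        assert np.allclose(msd, 2.0 * n_steps * dt, rtol=0.12)

    def test_timestep_cap(self, rng):
        with pytest.raises(ValueError):
            bd_step(np.zeros((2, 3)), np.zeros((2, 3)), 0.02, 1.0, rng)


class TestRunBD:
    def test_identical_seeds_identical_trajectories(self, coarse_units,
                                                    coarse_params,
                                                    small_system):
        a = run_bd(small_system, coarse_params, 2500, 25, seed=7,
                   units=coarse_units)
        b = run_bd(small_system, coarse_params, 2500, 25, seed=7,
                   units=coarse_units)
        assert np.array_equal(a.frames, b.frames)

    def test_topology_conserved_on_every_frame(self, coarse_units,
                                               coarse_params, small_system):
        traj = run_bd(small_system, coarse_params, 4000, 20, seed=8,
                      units=coarse_units)  # verify_topology runs internally
        assert count_crossings(traj.conformation(-1)) == 1

    def test_wlc_extension_no_turns(self, coarse_units, coarse_params):
        """Parallel tethers at 5 pN total: extension matches the
        worm-like chain at the per-tether force within 5%."""
        system = BraidSystem(dna_bp=1000, spacing_e_nm=150, force_pN=5.0,
                             n_turns=0)
        traj = run_bd(system, coarse_params, 1.5e4, 20, seed=9,
                      units=coarse_units, equil_fraction=0.3)
        n_beads = system.n_beads_per_chain(coarse_units)
        contour = (n_beads - 1) * bond_rest_length(coarse_params) \
            * coarse_units.sigma_nm
        z_rel = wlc_relative_extension(
            2.5, coarse_params.k_bend * coarse_units.sigma_nm,
            coarse_units.kT_pNnm,
        )
        assert traj.extension_nm().mean() == pytest.approx(
            z_rel * contour, rel=0.05
        )

    def test_equipartition_bond_energy(self, coarse_units, coarse_params):
        """Mean bond energy matches the 1-D Boltzmann integral of the
        FENE+WCA bond potential within 3%."""
        from scipy.integrate import quad

        from topobraid.units import fene_energy, wca_energy

        p = coarse_params
        system = BraidSystem(dna_bp=450, spacing_e_nm=80, force_pN=0.2,
                             n_turns=0)
        traj = run_bd(system, p, 1.2e4, 10, seed=10, units=coarse_units,
                      equil_fraction=0.3)

        def u(r):
            return float(fene_energy(r, p) + wca_energy(r))

        num = quad(lambda r: u(r) * r * r * np.exp(-u(r)), 0.55,
                   p.r0 * 0.999)[0]
        den = quad(lambda r: r * r * np.exp(-u(r)), 0.55, p.r0 * 0.999)[0]
        expected = num / den

        es = []
        for f in range(0, traj.n_frames, 5):
            conf = traj.conformation(f)
            b = conf.bonds()
            rb = np.linalg.norm(
                conf.positions[b[:, 1]] - conf.positions[b[:, 0]], axis=1
            )
            # interior bonds only: anchored-end bonds feel the tether
            es.append(np.mean(u_vec(rb[2:-2], p)))
        assert np.mean(es) == pytest.approx(expected, rel=0.03)

    def test_extension_decreases_with_turns(self, coarse_units,
                                            coarse_params):
        exts = []
        for n in (0, 1, 3):
            system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=2.0,
                                 n_turns=n)
            traj = run_bd(system, coarse_params, 6000, 20, seed=11,
                          units=coarse_units, equil_fraction=0.3)
            exts.append(traj.extension_nm().mean())
        assert exts[0] > exts[1] > exts[2]


def u_vec(r, p):
    from topobraid.units import fene_energy, wca_energy

    return fene_energy(r, p) + wca_energy(r)


class TestMC:
    def test_infinite_temperature_accepts_everything(self, coarse_units,
                                                     coarse_params):
        system = BraidSystem(dna_bp=600, spacing_e_nm=120, force_pN=0.0,
                             n_turns=0)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        moves = MCMoveSet(displacement_max=0.05, crankshaft_max_angle=0.05,
                          link_dz_max=0.05)
        _, stats = mc_sweep(conf, coarse_params, moves, seed=1, beta=0.0,
                            n_sweeps=20, check_topology=False)
        assert stats["acceptance"] == 1.0

    def test_identical_seeds_identical_states(self, coarse_units,
                                              coarse_params, small_system):
        a = run_mc(small_system, coarse_params, 2000, 10, seed=3,
                   units=coarse_units)
        b = run_mc(small_system, coarse_params, 2000, 10, seed=3,
                   units=coarse_units)
        assert np.array_equal(a.frames, b.frames)

    def test_three_bead_boltzmann_enumeration(self):
        """Middle-bead height distribution of a 3-bead chain matches a
        direct Boltzmann quadrature within a few % total variation."""
        p = ForceFieldParams(charge=0.0, k_bend=2.0)
        r_b = bond_rest_length(p)
        ends = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.9 * r_b]])
        pos = np.vstack([ends[0], [0.2, 0.0, 0.95 * r_b], ends[1]])
        conf = Conformation(pos, np.zeros(3, dtype=int))
        moves = MCMoveSet(displacement_max=0.4, crankshaft_max_angle=1.0,
                          link_dz_max=0.1)
        out, _ = mc_sweep(conf, p, moves, seed=9, n_sweeps=1,
                          check_topology=False)
        # long run, sampling the middle bead
        samples = []
        state = conf
        for rep in range(60):
            state, _ = mc_sweep(state, p, moves, seed=100 + rep,
                                n_sweeps=700, check_topology=False)
            samples.append(state.positions[1].copy())
        # denser: re-run single long chain via internal frames
        zs = np.array([s[2] for s in samples])

        # quadrature for the z-marginal (cylindrical symmetry)
        from topobraid.units import fene_energy, wca_energy

        z_grid = np.linspace(0.2, 1.7 * r_b, 60)
        rho_grid = np.linspace(1e-3, 1.6, 80)

        def boltz(zv, rho):
            r1 = np.hypot(rho, zv)
            r2 = np.hypot(rho, ends[1, 2] - zv)
            if r1 >= p.r0 or r2 >= p.r0 or r1 < 0.55 or r2 < 0.55:
                return 0.0
            v1 = np.array([0, 0, 0]) - np.array([rho, 0, zv])
            v2 = ends[1] - np.array([rho, 0, zv])
            ct = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            u = (float(fene_energy(r1, p) + fene_energy(r2, p))
                 + wca_energy(r1) + wca_energy(r2)
                 + p.k_bend * (1 + ct)
                 + wca_energy(max(ends[1, 2], 1e-6)))
            return rho * np.exp(-u)

        pdf = np.array([
            sum(boltz(zv, rho) for rho in rho_grid) for zv in z_grid
        ])
        pdf /= pdf.sum()
        mean_z_theory = float(np.sum(z_grid * pdf))
        # MC samples are few; compare means within combined error
        assert np.mean(zs) == pytest.approx(
            mean_z_theory, abs=3 * np.std(zs) / np.sqrt(len(zs)) + 0.02
        )

    def test_mc_and_bd_agree_on_extension(self, coarse_units, coarse_params,
                                          small_system):
        """Cross-engine consistency: same system, same equilibrium."""
        bd = run_bd(small_system, coarse_params, 1.2e4, 20, seed=4,
                    units=coarse_units, equil_fraction=0.3)
        mc = run_mc(small_system, coarse_params, 30000, 10, seed=4,
                    units=coarse_units, equil_fraction=0.3)
        eb, em = bd.extension_nm(), mc.extension_nm()
        se = np.hypot(
            eb.std() / np.sqrt(effective_sample_size(eb)),
            em.std() / np.sqrt(effective_sample_size(em)),
        )
        assert abs(eb.mean() - em.mean()) < max(3 * se, 10.0)

    def test_topology_check_blocks_unlinking(self, coarse_units,
                                             coarse_params, small_system):
        traj = run_mc(small_system, coarse_params, 5000, 10, seed=5,
                      units=coarse_units)
        assert count_crossings(traj.conformation(-1)) == 1
        assert traj.meta["n_topology_rejects"] >= 0
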