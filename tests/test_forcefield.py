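"""Force-field correctness: frozen values, brute-force and
finite-difference oracles, cutoff exactness, invariances."""

import math

import numpy as np
import pytest

from topobraid import (
    Conformation,
    ForceFieldParams,
    UnitSystem,
    bend_energy,
    dh_energy,
    fene_energy,
    forces,
    total_energy,
    wca_energy,
)
from topobraid.units import BondDomainError, bond_rest_length

from conftest import random_conformation


# ---------------------------------------------------------------------------
# single-potential values
# ---------------------------------------------------------------------------

class TestFene:
    def test_zero_extension_is_zero(self, defaults):
        assert fene_energy(0.0, defaults) == 0.0

    def test_value_at_unit_length(self, defaults):
        # -0.5 * 30 * 1.6^2 * ln(1 - (1/1.6)^2) = -38.4 ln(0.609375)
        expected = -38.4 * math.log(0.609375)
        assert fene_energy(1.0, defaults) == pytest.approx(expected, rel=1e-12)
        assert fene_energy(1.0, defaults) == pytest.approx(19.03, abs=0.01)

    def test_maximum_extension_is_domain_error(self, defaults):
        with pytest.raises(BondDomainError):
            fene_energy(1.6, defaults)
        with pytest.raises(BondDomainError):
            fene_energy(1.7, defaults)


class TestBend:
    @pytest.mark.parametrize(
        "theta,expected",
        [(math.pi, 0.0), (math.pi / 2, 20.0), (0.0, 40.0)],
    )
    def test_reference_angles(self, defaults, theta, expected):
        assert bend_energy(theta, defaults) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_out_of_range_rejected(self, defaults):
        with pytest.raises(ValueError):
            bend_energy(-0.1, defaults)
        with pytest.raises(ValueError):
            bend_energy(math.pi + 0.1, defaults)


class TestWca:
    def test_cutoff_continuity(self):
        cut = 2.0 ** (1.0 / 6.0)
        assert wca_energy(cut) == 0.0
        assert wca_energy(cut + 1e-9) == 0.0
        assert wca_energy(cut - 1e-6) == pytest.approx(0.0, abs=1e-9)

    def test_unit_separation(self):
        # LJ terms cancel at r = 1, the +1 shift remains
        assert wca_energy(1.0) == pytest.approx(1.0, rel=1e-12)

    def test_repulsive_value(self):
        expected = 4.0 * (0.9**-12 - 0.9**-6) + 1.0
        assert wca_energy(0.9) == pytest.approx(expected, rel=1e-12)
        assert wca_energy(0.9) == pytest.approx(7.636, abs=0.001)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            wca_energy(0.0)


class TestDebyeHueckel:
    def test_zero_at_and_beyond_cutoff(self, defaults):
        q = defaults.charge
        assert dh_energy(6.0, q, q, defaults) == 0.0
        assert dh_energy(8.0, q, q, defaults) == 0.0

    def test_no_charge_no_interaction(self, defaults):
        assert dh_energy(1.0, 0.0, defaults.charge, defaults) == 0.0

    def test_contact_value_matches_closed_form(self, defaults):
        # lb q^2/(eps r) exp(-r/lambda) at r = 1 sigma, default params
        q = defaults.charge
        expected = (defaults.bjerrum_sigma * q * q / defaults.epsilon
                    * math.exp(-1.0 / defaults.screening_sigma))
        assert dh_energy(1.0, q, q, defaults) == pytest.approx(expected,
                                                               rel=1e-12)
        # frozen value for the shipped defaults
        assert dh_energy(1.0, q, q, defaults) == pytest.approx(0.110664,
                                                               abs=2e-5)

    def test_screening_monotone_decay(self, defaults):
        q = defaults.charge
        r = np.linspace(0.5, 5.5, 40)
        u = dh_energy(r, q, q, defaults)
        assert np.all(np.diff(u) < 0)


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------

def brute_force_energy(c: Conformation, p: ForceFieldParams) -> float:
    """Independent O(n^2) summation written directly from the model
    definition (FENE bonds, cosine bends, WCA all pairs, DH non-bonded)."""
    pos = c.positions
    cid = c.chain_ids
    n = len(pos)
    e = 0.0
    for i in range(n - 1):
        if cid[i] == cid[i + 1]:
            r = np.linalg.norm(pos[i + 1] - pos[i])
            e += -0.5 * p.k_fene * p.r0**2 * math.log(1 - (r / p.r0) ** 2)
    for j in range(1, n - 1):
        if cid[j - 1] == cid[j] == cid[j + 1]:
            a = pos[j - 1] - pos[j]
            b = pos[j + 1] - pos[j]
            ct = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            e += p.k_bend * (1 + ct)
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(pos[i] - pos[j])
            if r < 2 ** (1 / 6):
                e += 4 * (r**-12 - r**-6) + 1
            bonded = j == i + 1 and cid[i] == cid[j]
            if p.use_dh and not bonded and r < p.dh_cutoff_sigma:
                e += (p.bjerrum_sigma * p.charge**2 / (p.epsilon * r)
                      * math.exp(-r / p.screening_sigma))
    return e


class TestTotalEnergy:
    def test_straight_separated_chains_bonded_terms_only(self, defaults):
        """Two straight chains >6 sigma apart at the FENE+WCA minimum:
        only bond terms survive (charges off isolates the identity)."""
        p = ForceFieldParams(charge=0.0)
        r_star = bond_rest_length(p)
        n = 6
        z = np.arange(n) * r_star
        pos = np.vstack([
            np.column_stack([np.zeros(n), np.zeros(n), z]),
            np.column_stack([np.full(n, 10.0), np.zeros(n), z]),
        ])
        c = Conformation(pos, np.repeat([0, 1], n))
        per_bond = float(fene_energy(r_star, p) + wca_energy(r_star))
        assert total_energy(c, p) == pytest.approx(2 * (n - 1) * per_bond,
                                                   rel=1e-10)

    def test_rigid_motion_invariance(self, defaults, rng):
        c = random_conformation(rng)
        e0 = total_energy(c, defaults)
        shifted = Conformation(c.positions + np.array([5.0, 5.0, 5.0]),
                               c.chain_ids)
        assert total_energy(shifted, defaults) == pytest.approx(e0, abs=1e-9)
        theta = 0.7
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        rotated = Conformation(c.positions @ rot.T, c.chain_ids)
        assert total_energy(rotated, defaults) == pytest.approx(e0, abs=1e-9)

    @pytest.mark.parametrize("n_chains", [1, 2])
    def test_matches_brute_force(self, defaults, rng, n_chains):
        for _ in range(5):
            c = random_conformation(rng, n_per_chain=4, n_chains=n_chains)
            assert total_energy(c, defaults) == pytest.approx(
                brute_force_energy(c, defaults), rel=1e-10
            )

    def test_kernel_energy_matches_reference(self, defaults, rng):
        """The compiled engine energy agrees with the numpy reference."""
        from topobraid import _kernels

        c = random_conformation(rng, n_per_chain=6)
        e_ref = total_energy(c, defaults)
        e_kern = _kernels.total_energy_kernel(
            c.positions, c.chain_ids, defaults.k_fene, defaults.r0,
            defaults.k_bend, defaults.use_dh, defaults.dh_prefactor,
            defaults.screening_sigma, defaults.dh_cutoff_sigma,
            defaults.wca_sigma**2,
        )
        assert e_kern == pytest.approx(e_ref, rel=1e-10)

    def test_kernel_energy_with_thin_excluded_volume(self, rng):
        """Kernel/reference agreement with a non-bonded diameter below
        the bead spacing (the discrete-WLC braid profile)."""
        from topobraid import _kernels

        p = ForceFieldParams(charge=0.0, wca_sigma=0.4, k_bend=3.3)
        c = random_conformation(rng, n_per_chain=6, params=p)
        e_ref = total_energy(c, p)
        e_kern = _kernels.total_energy_kernel(
            c.positions, c.chain_ids, p.k_fene, p.r0, p.k_bend,
            False, 0.0, p.screening_sigma, p.dh_cutoff_sigma,
            p.wca_sigma**2,
        )
        assert e_kern == pytest.approx(e_ref, rel=1e-10)


class TestForces:
    def test_interior_beads_at_rest_have_no_force(self):
        p = ForceFieldParams(charge=0.0)
        r_star = bond_rest_length(p)
        z = np.arange(8) * r_star
        c = Conformation(np.column_stack([np.zeros(8), np.zeros(8), z]),
                         np.zeros(8, dtype=int))
        f = forces(c, p)
        assert np.abs(f[2:-2]).max() < 1e-8

    def test_finite_difference_gradient(self, defaults, rng):
        """-grad(U) check on 100 random conformations."""
        h = 1e-6
        for _ in range(100):
            c = random_conformation(rng, n_per_chain=4)
            f = forces(c, defaults)
            scale = max(1.0, np.abs(f).max())
            k = int(rng.integers(len(c.positions)))
            d = int(rng.integers(3))
            for sign in (1,):
                cp = c.copy()
                cp.positions[k, d] += h
                cm = c.copy()
                cm.positions[k, d] -= h
                fd = -(total_energy(cp, defaults)
                       - total_energy(cm, defaults)) / (2 * h)
                assert f[k, d] == pytest.approx(fd, abs=2e-5 * scale)

    def test_newtons_third_law(self, defaults, rng):
        c = random_conformation(rng, n_per_chain=5)
        f = forces(c, defaults)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_zero_torque(self, defaults, rng):
        c = random_conformation(rng, n_per_chain=5)
        f = forces(c, defaults)
        torque = np.cross(c.positions, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-9


# ---------------------------------------------------------------------------
# parameters & config
# ---------------------------------------------------------------------------

class TestParams:
    def test_thermal_energy_consistency(self):
        u = UnitSystem(temperature_K=293.0)
        assert u.kT_pNnm == pytest.approx(0.0138 * 293.0, rel=1e-3)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ForceFieldParams(r0=2.5)
        with pytest.raises(ValueError):
            ForceFieldParams(k_fene=-1.0)
        with pytest.raises(ValueError):
            UnitSystem(sigma_nm=-1.0)

    def test_config_round_trip(self, defaults, fine_units):
        text = defaults.to_config(fine_units)
        p2, u2 = ForceFieldParams.from_config(text)
        assert p2 == defaults
        assert u2 == fine_units

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ForceFieldParams.from_config("k_fene=30\nbogus_key=1\n")

    def test_coarse_profile_keeps_persistence_length(self, coarse_units,
                                                     coarse_params):
        lp_nm = coarse_params.k_bend * coarse_units.sigma_nm
        assert lp_nm == pytest.approx(50.0, rel=1e-6)

    def test_bond_rest_length_near_wca_minimum(self, defaults):
        r = bond_rest_length(defaults)
        assert 0.9 < r < 1.0
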