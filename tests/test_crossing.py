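"""Juxtaposition detection, crossing angles, and crossing counting."""

import numpy as np
import pytest

from topobraid import (
    BraidSystem,
    Conformation,
    UnitSystem,
    build_initial_braid,
    count_crossings,
    crossing_angle,
    min_interchain_segments,
    mirror_distribution,
)
from topobraid.crossing import (
    UndefinedAngleError,
    angle_distribution,
    closest_approach_table,
    distribution_from_angles,
)
from topobraid.system import Trajectory
from topobraid.units import ForceFieldParams


def two_chain_conf(pos_a, pos_b):
    pos = np.vstack([pos_a, pos_b])
    cid = np.repeat([0, 1], [len(pos_a), len(pos_b)])
    return Conformation(pos, cid)


def straight(start, end, n=5):
    return np.linspace(start, end, n)


class TestMinDistance:
    def test_parallel_chains(self):
        a = straight([0, 0, 0], [0, 0, 10])
        b = straight([20, 0, 0], [20, 0, 10])
        conf = two_chain_conf(a, b)
        d, _, _, _ = min_interchain_segments(conf)
        assert d == pytest.approx(20.0)

    def test_perpendicular_skew_lines(self):
        a = straight([-5, 0, 0], [5, 0, 0])
        b = straight([0, -5, 3], [0, 5, 3])
        conf = two_chain_conf(a, b)
        d, sa, sb, (pa, pb) = min_interchain_segments(conf)
        assert d == pytest.approx(3.0)
        assert pa[:2] == pytest.approx([0.0, 0.0], abs=1e-9)
        assert pb[2] - pa[2] == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        def seg_dist(p0, p1, q0, q1, m=201):
            s = np.linspace(0, 1, m)
            pa = p0 + s[:, None] * (p1 - p0)
            qa = q0 + s[:, None] * (q1 - q0)
            d = pa[:, None, :] - qa[None, :, :]
            return np.sqrt((d**2).sum(-1)).min()

        for _ in range(10):
            a = np.cumsum(rng.normal(size=(5, 3)), axis=0)
            b = np.cumsum(rng.normal(size=(5, 3)), axis=0) + [3, 0, 0]
            conf = two_chain_conf(a, b)
            d, sa, sb, _ = min_interchain_segments(conf)
            brute = min(
                seg_dist(a[i], a[i + 1], b[j], b[j + 1])
                for i in range(4)
                for j in range(4)
            )
            assert d == pytest.approx(brute, abs=2e-3)

    def test_distance_scaling(self):
        a = straight([0, 0, 0], [0, 0, 10])
        b = straight([4, 0, 0], [4, 0, 10])
        conf = two_chain_conf(a, b)
        d_nm, _, _, _ = min_interchain_segments(conf, sigma_nm=2.5)
        assert d_nm == pytest.approx(10.0)


class TestCrossingAngle:
    def test_orthogonal_crossing_is_90(self):
        assert crossing_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_flipping_over_under_gives_supplement(self):
        # moving the top strand underneath reverses the juxtaposition
        # axis: the angle becomes the supplement
        a = crossing_angle([1, 0, 0.2], [0.3, 1, 0.2], gap=[0, 0, 1])
        b = crossing_angle([1, 0, 0.2], [0.3, 1, 0.2], gap=[0, 0, -1])
        assert a + b == pytest.approx(180.0)

    def test_constructed_45_clockwise(self):
        c45 = np.cos(np.radians(45))
        assert crossing_angle([1, 0, 0], [c45, -c45, 0]) == pytest.approx(45.0)

    def test_parallel_tangents_undefined(self):
        with pytest.raises(UndefinedAngleError):
            crossing_angle([1, 0, 0], [1, 1e-9, 0])

    def test_result_invariant_under_strand_exchange(self):
        """The reported angle does not depend on which strand is called
        'bottom' (both the cross product and the axis flip)."""
        u, v, gap = [1, 0.1, 0.5], [-0.9, 0.2, 0.6], [0.1, -0.9, 0.3]
        a = crossing_angle(u, v, gap=gap)
        b = crossing_angle(v, u, gap=[-g for g in gap])
        assert a == pytest.approx(b)


class TestCountCrossings:
    def test_straight_parallel_chains_zero(self):
        a = straight([0, 0, 0], [0, 0, 30], 8)
        b = straight([10, 0, 0], [10, 0, 30], 8)
        assert count_crossings(two_chain_conf(a, b)) == 0

    @pytest.mark.parametrize("n_turns", [2, -2, 1, -3])
    def test_built_braids(self, coarse_units, coarse_params, n_turns):
        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=n_turns)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        assert count_crossings(conf) == n_turns

    def test_matches_brute_force_oracle(self, coarse_units, coarse_params,
                                        rng):
        """Signed sum over segment pairs computed independently in
        python with the same projection convention."""
        from topobraid.crossing import _TOPO_SIGN

        system = BraidSystem(dna_bp=600, spacing_e_nm=80, force_pN=1.0,
                             n_turns=2)
        conf = build_initial_braid(system, coarse_units, coarse_params)
        pos = conf.positions + rng.normal(scale=0.01, size=conf.positions.shape)
        n1 = int((conf.chain_ids == 0).sum())

        def brute(pos):
            # project onto xz, depth y
            total = 0
            for a in range(n1 - 1):
                for b in range(n1, len(pos) - 1):
                    p0, p1 = pos[a, [0, 2]], pos[a + 1, [0, 2]]
                    q0, q1 = pos[b, [0, 2]], pos[b + 1, [0, 2]]
                    da, db = p1 - p0, q1 - q0
                    den = da[0] * db[1] - da[1] * db[0]
                    if den == 0:
                        continue
                    t = ((q0 - p0)[0] * db[1] - (q0 - p0)[1] * db[0]) / den
                    u = ((q0 - p0)[0] * da[1] - (q0 - p0)[1] * da[0]) / den
                    if not (0 <= t < 1 and 0 <= u < 1):
                        continue
                    ya = pos[a, 1] + t * (pos[a + 1, 1] - pos[a, 1])
                    yb = pos[b, 1] + u * (pos[b + 1, 1] - pos[b, 1])
                    s = 1 if den > 0 else -1
                    total += -s if ya > yb else s
            return total

        assert count_crossings((pos, n1)) == _TOPO_SIGN * brute(pos)


def synthetic_trajectory(angle_deg=90.0, n_frames=150, dist_sigma=1.5,
                         jitter=0.02, seed=0, units=None):
    """Frames of two straight chains crossing at a fixed angle."""
    rng = np.random.default_rng(seed)
    units = units or UnitSystem.coarse(5.0)
    half = np.radians(angle_deg / 2.0)
    n = 7
    frames = []
    for _ in range(n_frames):
        # horizontal strands rotated +-angle/2 about z, stacked along z
        ta = np.array([np.cos(-half + np.pi / 2), np.sin(-half + np.pi / 2), 0.0])
        tb = np.array([np.cos(half + np.pi / 2), np.sin(half + np.pi / 2), 0.0])
        a = np.linspace(-3 * ta, 3 * ta, n) + [0, 0, 5.0]
        b = np.linspace(-3 * tb, 3 * tb, n) + [0, 0, 5.0 + dist_sigma]
        f = np.vstack([a, b]) + rng.normal(scale=jitter, size=(2 * n, 3))
        frames.append(f)
    cid = np.repeat([0, 1], n)
    return Trajectory(
        frames=np.asarray(frames), chain_ids=cid, sample_interval=1.0,
        seed=seed, units=units, params=ForceFieldParams(),
    )


class TestAngleDistribution:
    def test_delta_geometry_concentrates(self):
        traj = synthetic_trajectory(angle_deg=90.0)
        dist = angle_distribution(traj, threshold_nm=10.0, min_frames=100,
                                  tangent_halfwidth=1)
        in_band = dist.counts[
            (dist.bin_centers_deg > 86) & (dist.bin_centers_deg < 94)
        ].sum()
        assert in_band / dist.counts.sum() > 0.95

    def test_threshold_monotonicity(self):
        traj = synthetic_trajectory(dist_sigma=2.0, jitter=0.3, seed=3)
        tab = closest_approach_table(traj)
        n_qual = [
            (tab.min_distance_nm <= thr).sum() for thr in (6.0, 10.0, 14.0)
        ]
        assert n_qual[0] <= n_qual[1] <= n_qual[2]

    def test_insufficient_frames_raises(self):
        from topobraid.crossing import InsufficientSamplingError

        traj = synthetic_trajectory(n_frames=30)
        with pytest.raises(InsufficientSamplingError):
            angle_distribution(traj, min_frames=100)

    def test_mirrored_trajectory_mirrors_distribution(self):
        """Reflecting all frames through the xz-plane flips the
        chirality: the measured distribution equals the mirror."""
        traj = synthetic_trajectory(angle_deg=70.0, jitter=0.05, seed=5)
        dist = angle_distribution(traj, min_frames=100, tangent_halfwidth=1)
        mirrored_frames = traj.frames.copy()
        mirrored_frames[:, :, 1] *= -1.0
        traj_m = Trajectory(
            frames=mirrored_frames, chain_ids=traj.chain_ids,
            sample_interval=1.0, seed=0, units=traj.units,
            params=traj.params,
        )
        dist_m = angle_distribution(traj_m, min_frames=100,
                                    tangent_halfwidth=1)
        assert np.allclose(dist_m.counts, mirror_distribution(dist).counts)

    def test_bootstrap_sem_shrinks_with_n(self, rng):
        sems = []
        for n in (400, 6400):
            means = []
            base = rng.normal(80, 10, n)
            for _ in range(100):
                means.append(np.mean(rng.choice(base, n)))
            sems.append(np.std(means))
        assert sems[1] < sems[0] / 2.5


class TestMirrorDistribution:
    def test_symmetric_input_unchanged(self, rng):
        angles = np.concatenate([rng.normal(70, 5, 5000),
                                 rng.normal(110, 5, 5000)])
        d = distribution_from_angles(angles)
        m = mirror_distribution(d)
        # statistically symmetric: totals preserved, mass mirrored
        assert m.counts.sum() == d.counts.sum()

    def test_mass_relocation(self):
        d = distribution_from_angles(np.full(100, 75.0))
        m = mirror_distribution(d)
        centers = m.bin_centers_deg
        assert m.counts[(centers > 100) & (centers < 110)].sum() == 100

    def test_double_mirror_is_identity(self, rng):
        d = distribution_from_angles(rng.uniform(0, 180, 2000))
        mm = mirror_distribution(mirror_distribution(d))
        assert np.array_equal(mm.counts, d.counts)
        assert np.allclose(mm.density, d.density)

    def test_asymmetric_grid_rejected(self):
        from topobraid.crossing import AngleDistribution

        edges = np.linspace(10, 170, 17)
        counts = np.ones(16, dtype=np.int64)
        density = counts / counts.sum() / np.diff(edges)
        d = AngleDistribution(edges, density, counts, 16)
        with pytest.raises(ValueError):
            mirror_distribution(d)
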