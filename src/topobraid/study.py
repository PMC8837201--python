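"""Scaled-down reproduction of the headline computations.

Drives the package end to end at desk-scale problem sizes: Monte Carlo
and Brownian-dynamics sampling of the single-crossing exemplar geometry
(3 kb tethers, 624 nm anchor spacing, 1 pN total force), crossing-angle
distributions, chirality-resolved unlinking kinetics, and the
preferred-angle inference, plus the analytic plectoneme step size and
the rate-law fits on synthetic data generated at the published kinetic
parameters.  Problem sizes (sweep counts, trajectory lengths, bead
sizes) are the package's reduced defaults; the full-fidelity protocol
is available through the engine APIs directly.
"""

from __future__ import annotations

import numpy as np

from .bd import run_bd
from .crossing import (
    angle_distribution,
    closest_approach_table,
    distribution_from_angles,
    mirror_distribution,
)
from .kinetics import (
    combine_geometries,
    fit_exponential,
    fit_inverse_dwell,
    fit_michaelis_menten,
    infer_preferred_angle,
    tau_ratio,
)
from .mc import MCMoveSet, braid_mc_profile, run_mc
from .mechanics import TetherGeometry, plectoneme_slope
from .synth import (
    gen_mm_dataset,
    gen_single_crossing_assay,
    gen_supercoil_relaxation,
)
from .system import BraidSystem
from .traces import ttest_stepfind
from .units import ForceFieldParams, UnitSystem

__all__ = [
    "EXEMPLAR",
    "mc_positive_crossing",
    "bd_crossing_angles",
    "preferred_angle_mc",
    "preferred_angle_bd",
    "tau_ratio_synthetic",
    "combined_preferred_angle",
    "plectoneme_step_nm",
    "mm_fit_synthetic",
    "inverse_dwell_synthetic",
    "stepfinder_recall",
    "persistence_length_bd",
]

#: the single-crossing assay geometry of the exemplar tether pair
EXEMPLAR = BraidSystem(dna_bp=3000, spacing_e_nm=624.0, force_pN=1.0,
                      n_turns=+1)

#: published chirality-resolved unlinking times of the exemplar (s)
TAU_L_S = 8.4
TAU_R_S = 43.8

MC_SWEEPS = 120_000
MC_SAMPLE_EVERY = 10
BD_TOTAL_TAU = 3.5e4
BD_SAMPLE_TAU = 10.0
BD_SEGMENT_NM = 12.0
BD_WCA_SIGMA = 0.7      # 8.4 nm effective diameter at 12 nm beads


def _mc_moves() -> MCMoveSet:
    return MCMoveSet(displacement_max=0.35, crankshaft_max_angle=1.6,
                     link_dz_max=1.0, move_weights=(0.45, 0.40, 0.15))


def mc_positive_crossing(seed: int, n_sweeps: int = MC_SWEEPS,
                         system: BraidSystem | None = None):
    """MC trajectory and angle distribution of the positive crossing."""
    units, params = braid_mc_profile()
    traj = run_mc(system or EXEMPLAR, params, n_sweeps, MC_SAMPLE_EVERY,
                  seed=seed, units=units, equil_fraction=0.2,
                  moves=_mc_moves())
    dist = angle_distribution(traj)
    return dist, traj


def bd_crossing_angles(seed: int, total_tau: float = BD_TOTAL_TAU):
    """Chirality-aligned crossing angles from +1 and -1 BD runs.

    The negative-crossing angles are reflected onto the positive
    convention (alpha -> 180 - alpha), doubling the statistics for the
    positive-crossing distribution, whose mirror supplies P_R.
    """
    units = UnitSystem.coarse(BD_SEGMENT_NM)
    params = ForceFieldParams.for_units(units, wca_sigma=BD_WCA_SIGMA)
    angles = []
    for k, n in enumerate((+1, -1)):
        system = BraidSystem(dna_bp=EXEMPLAR.dna_bp,
                             spacing_e_nm=EXEMPLAR.spacing_e_nm,
                             force_pN=EXEMPLAR.force_pN, n_turns=n)
        traj = run_bd(system, params, total_tau, BD_SAMPLE_TAU,
                      seed=seed + k, units=units, equil_fraction=0.2)
        tab = closest_approach_table(traj)
        sel = tab[(tab.min_distance_nm <= 10.0)
                  & np.isfinite(tab.angle_deg)]
        a = sel.angle_deg.to_numpy()
        angles.append(a if n > 0 else 180.0 - a)
    return np.concatenate(angles)


def tau_ratio_synthetic(seed: int, n_cycles: int = 200):
    """tau_L/tau_R recovered from a synthetic single-crossing assay
    generated at the published time constants."""
    _, truth = gen_single_crossing_assay(TAU_L_S, TAU_R_S,
                                         n_cycles=n_cycles,
                                         sample_rate_hz=20.0, seed=seed)
    f_L = fit_exponential(truth.extras["waits_L_s"])
    f_R = fit_exponential(truth.extras["waits_R_s"])
    return tau_ratio(f_L, f_R)


def preferred_angle_mc(dist, rho: float, se_rho: float, seed: int = 0):
    """alpha0 from the MC positive-crossing distribution and its mirror."""
    return infer_preferred_angle(dist, mirror_distribution(dist), rho,
                                 se_rho, n_bootstrap=100, seed=seed,
                                 method="MC")


def preferred_angle_bd(angles: np.ndarray, rho: float, se_rho: float,
                       bin_deg: float = 4.0, seed: int = 0):
    """alpha0 from pooled BD angles (coarser bins: fewer events)."""
    P_L = distribution_from_angles(angles, bin_deg=bin_deg)
    return infer_preferred_angle(P_L, mirror_distribution(P_L), rho,
                                 se_rho, n_bootstrap=100, seed=seed,
                                 method="BD")


def combined_preferred_angle(dist, alpha_star: float = 87.5,
                             n_geometries: int = 14, n_cycles: int = 60,
                             seed: int = 0):
    """Planted-angle recovery across synthetic tether geometries.

    Stand-in for the multi-geometry average: each synthetic geometry
    draws chirality-resolved unlinking times whose rate ratio is set by
    the crossing-angle densities at the planted preferred angle
    alpha_star, runs the exponential fits, and re-infers alpha0; the
    unweighted mean and SEM across geometries are returned.
    """
    rng = np.random.default_rng(seed)
    P_R = mirror_distribution(dist)
    # planted ratio: log-density ratio interpolated at alpha_star over
    # the supported bins (the same representation the inference inverts)
    ok = (dist.counts >= 5) & (P_R.counts >= 5)
    centers = dist.bin_centers_deg[ok]
    log_ratio = np.log(P_R.density[ok]) - np.log(dist.density[ok])
    rho_star = float(np.exp(np.interp(alpha_star, centers, log_ratio)))
    results = []
    g = 0
    while len(results) < n_geometries and g < 3 * n_geometries:
        g += 1
        waits_L = rng.exponential(TAU_L_S, n_cycles)
        waits_R = rng.exponential(TAU_L_S / rho_star, n_cycles)
        rho, se = tau_ratio(fit_exponential(waits_L),
                            fit_exponential(waits_R))
        try:
            res = infer_preferred_angle(dist, P_R, rho, se,
                                        n_bootstrap=0, systematic=False)
        except Exception:
            continue
        results.append(res)
    return combine_geometries(results)


def plectoneme_step_nm(force_pN: float = 0.4) -> float:
    """Extension released by one strand-passage event (Delta Lk = 2) on
    a plectonemic tether at the given force, 100 mM salt, Lp = 50 nm."""
    g = TetherGeometry(contour_length_nm=1700.0, force_pN=force_pN)
    return 2.0 * plectoneme_slope(g)


def mm_fit_synthetic(seed: int, vmax: float = 21.4, kd_nM: float = 0.067):
    """Michaelis-Menten fit of a synthetic rate-vs-concentration set
    generated at the published positive-braid parameters."""
    conc, rates, _ = gen_mm_dataset(vmax=vmax, kd_app=kd_nM,
                                    noise_frac=0.05, n_rep=3, seed=seed)
    return fit_michaelis_menten(conc, rates)


def inverse_dwell_synthetic(seed: int, c_s: float = 10.0, n_traces: int = 40):
    """Inverse dwell-vs-crossing-number constant recovered from
    synthetic distributive supercoil relaxation."""
    ns, dwells = [], []
    for k in range(n_traces):
        _, truth = gen_supercoil_relaxation(n0_crossings=10,
                                            c_inverse_s=c_s,
                                            noise_sd_nm=0.0,
                                            sample_rate_hz=10.0,
                                            seed=seed + k)
        ns.extend(truth.extras["crossings"])
        dwells.extend(truth.extras["dwells_s"])
    c, se, _ = fit_inverse_dwell(ns, dwells)
    return c, se


def stepfinder_recall(seed: int, n_traces: int = 60, amp_nm: float = 100.0,
                      noise_sd: float = 20.0):
    """Detection recall of the t-test step finder at SNR = 5 with long
    dwells, over synthetic two-step traces."""
    rng = np.random.default_rng(seed)
    from .traces import Trace

    found = total = 0
    for _ in range(n_traces):
        levels = np.repeat([0.0, amp_nm, 2 * amp_nm], 400)
        y = levels + rng.normal(0, noise_sd, len(levels))
        trace = Trace(np.arange(len(y)) / 200.0, y, 200.0)
        steps = ttest_stepfind(trace, window=100)
        total += 2
        found += min(steps.n_steps, 2)
    return found / total


def persistence_length_bd(seed: int, total_tau: float = 8e3):
    """Persistence length of the fine-grained chain (2.5 nm beads,
    K_BEND = 20 kT) from the nearest-neighbour tangent correlation.

    Uses the discrete-chain estimator Lp = -b / ln<t_i . t_i+1> on
    interior segments of a long tether at moderate tension; long-lag
    fits conflate the bending stiffness with the end-anchoring of the
    tethered geometry, whereas the local estimator measures the joint
    bending distribution directly.
    """
    units = UnitSystem()
    params = ForceFieldParams()
    system = BraidSystem(dna_bp=1500, spacing_e_nm=400.0, force_pN=0.3,
                         n_turns=0)
    traj = run_bd(system, params, total_tau, 20.0, seed=seed, units=units,
                  equil_fraction=0.4, check_topology=False)
    n1 = traj.n_chain0
    acc = 0.0
    cnt = 0
    for f in range(traj.n_frames):
        for lo, hi in ((30, n1 - 30), (n1 + 30, 2 * n1 - 30)):
            seg = np.diff(traj.frames[f, lo:hi], axis=0)
            t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            acc += np.einsum("ij,ij->i", t[:-1], t[1:]).mean()
            cnt += 1
    from .units import bond_rest_length

    b = bond_rest_length(params)
    return float(-b * units.sigma_nm / np.log(acc / cnt))
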