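"""Brownian/Langevin dynamics of the braided-tether system.

The production integrator is an underdamped BAOAB Langevin thermostat
(unit mass, friction gamma) at the standard 0.01 tau timestep; the
overdamped Euler-Maruyama update

    x <- x + (F / gamma) dt + sqrt(2 kT dt / gamma) xi

is exposed as the :func:`bd_step` primitive and as an alternative
integrator for small timesteps (the stiff FENE+WCA bond core makes it
unstable at 0.01 tau).  Both sample the same Boltzmann ensemble, which
is all the equilibrium crossing-angle analysis needs.  Bottom anchor
beads are restrained by stiff harmonic springs; each chain's top
attachment bead is restrained laterally and carries half the bead force
along +z.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .system import BraidSystem, Trajectory, build_initial_braid
from .units import Conformation, ForceFieldParams, UnitSystem

__all__ = ["bd_step", "run_bd", "BDIntegrationError", "DEFAULT_DT_TAU"]

DEFAULT_DT_TAU = 0.01
ANCHOR_SPRING = 50.0  # kT/sigma^2; keeps k*dt/gamma well below stability limit


class BDIntegrationError(RuntimeError):
    """A FENE bond reached R0 during integration."""

    def __init__(self, step: int, bead: int, message: str | None = None):
        self.step = step
        self.bead = bead
        super().__init__(
            message or f"bond exploded at bead {bead}, step {step}"
        )


def bd_step(
    positions: np.ndarray,
    forces: np.ndarray,
    dt_tau: float,
    gamma: float,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> np.ndarray:
    """One Euler-Maruyama update given precomputed forces (kT/sigma).

    This is the integrator primitive; :func:`run_bd` drives the compiled
    production loop with identical arithmetic.
    """
    if dt_tau > DEFAULT_DT_TAU + 1e-12:
        raise ValueError(f"dt_tau must be <= {DEFAULT_DT_TAU}")
    positions = np.asarray(positions, dtype=float)
    step = forces * (dt_tau / gamma)
    if noise_scale:
        step = step + noise_scale * np.sqrt(2.0 * dt_tau / gamma) * rng.standard_normal(
            positions.shape
        )
    return positions + step


def run_bd(
    system: BraidSystem,
    params: ForceFieldParams,
    total_tau: float,
    sample_every_tau: float = 250.0,
    dt_tau: float = DEFAULT_DT_TAU,
    seed: int = 0,
    units: UnitSystem | None = None,
    gamma: float = 1.0,
    equil_fraction: float = 0.1,
    noise_scale: float = 1.0,
    initial: Conformation | None = None,
    check_topology: bool = True,
    integrator: str = "langevin",
    mass: float = 1.0,
) -> Trajectory:
    """Brownian/Langevin-dynamics trajectory of a braided tether pair.

    The default integrator is an underdamped BAOAB Langevin thermostat
    (unit mass, friction ``gamma``), stable at the standard 0.01 tau
    timestep; ``integrator="overdamped"`` selects plain Euler-Maruyama,
    which needs dt_tau <~ 0.002 for the stiff bond core.  Frames are
    stored every ``sample_every_tau``; the first ``equil_fraction`` of
    stored frames is discarded as equilibration.  The signed crossing
    number is verified on every stored frame.
    """
    if integrator not in ("langevin", "overdamped"):
        raise ValueError("integrator must be 'langevin' or 'overdamped'")
    if dt_tau > DEFAULT_DT_TAU + 1e-12:
        raise ValueError(f"dt_tau must be <= {DEFAULT_DT_TAU}")
    if total_tau < 100.0 * sample_every_tau:
        raise ValueError("total_tau must be >= 100 * sample_every_tau")
    units = units or UnitSystem()
    if initial is not None:
        conf = initial
    else:
        from .system import equilibrium_extension_estimate

        conf = build_initial_braid(
            system, units, params,
            extension_sigma=equilibrium_extension_estimate(
                system, units, params),
        )
    pos = conf.positions.copy()
    cid = conf.chain_ids.copy()
    n1 = int(np.sum(cid == 0))
    # force_pN is the total bead force, shared by the two tethers
    f_red = units.force_to_reduced(system.force_pN) / 2.0

    n_steps = int(round(total_tau / dt_tau))
    sample_every = max(1, int(round(sample_every_tau / dt_tau)))
    n_store = n_steps // sample_every
    frames = np.empty((n_store, pos.shape[0], 3))

    anchors_bot = np.asarray(conf.anchor_bottom, dtype=float)
    top_xy = np.asarray(conf.anchor_top, dtype=float)[:, :2].copy()

    if initial is None:
        # quiet overdamped settle: relaxes the strained junction bonds
        # of the freshly built conformation before production
        settle_frames = np.empty((0, pos.shape[0], 3))
        status, step = _kernels.run_bd_kernel(
            pos, cid, n1, anchors_bot, top_xy, f_red, ANCHOR_SPRING,
            params.k_fene, params.r0, params.k_bend,
            params.use_dh and params.charge != 0.0, params.dh_prefactor,
            params.screening_sigma, params.dh_cutoff_sigma,
            1e-3, gamma, 0.0, 6000, 10**9,
            int(seed) % (2**31 - 1), settle_frames, True, mass,
            params.wca_sigma**2, 0.02,
        )
        if status < 0:
            raise BDIntegrationError(step, -status,
                                     "settle phase failed: bond exploded")

    status, step = _kernels.run_bd_kernel(
        pos, cid, n1, anchors_bot, top_xy, f_red, ANCHOR_SPRING,
        params.k_fene, params.r0, params.k_bend,
        params.use_dh and params.charge != 0.0, params.dh_prefactor,
        params.screening_sigma, params.dh_cutoff_sigma,
        dt_tau, gamma, noise_scale, n_steps, sample_every,
        int(seed) % (2**31 - 1), frames, integrator == "overdamped", mass,
        params.wca_sigma**2, 0.2,
    )
    if status < 0:
        raise BDIntegrationError(step, -status)

    n_discard = int(round(equil_fraction * n_store))
    frames = frames[n_discard:]
    traj = Trajectory(
        frames=frames,
        chain_ids=cid,
        sample_interval=sample_every * dt_tau,
        seed=int(seed),
        units=units,
        params=params,
        system=system,
        meta={
            "engine": "bd",
            "dt_tau": dt_tau,
            "gamma": gamma,
            "total_tau": total_tau,
            "n_discarded": n_discard,
            "scaled_down": total_tau < 4.0e7,
        },
    )
    if check_topology and system.n_turns is not None:
        from .crossing import verify_topology

        verify_topology(traj, expected=system.n_turns)
    return traj
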