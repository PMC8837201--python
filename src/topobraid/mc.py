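"""Metropolis Monte Carlo sampling of the braided-tether system.

The move set keeps both chain endpoints anchored: single-bead
displacements, crankshaft rotations of a sub-chain about the chord
through its two (unmoved) pivot beads, and a rigid vertical move of the
two top attachment beads that carries the -F dz work term of the
applied force.  All proposals are symmetric, so the plain Metropolis
criterion on Delta U satisfies detailed balance.

Because Monte Carlo moves are non-physical paths, excluded volume alone
does not forbid the chains tunnelling through each other; an explicit
per-move topology check compares the signed projected-crossing
contribution of the displaced segments against the other chain and
rejects any move that would change the catenation number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .system import BraidSystem, Trajectory, build_initial_braid, effective_sample_size
from .units import Conformation, ForceFieldParams, UnitSystem

__all__ = ["MCMoveSet", "mc_sweep", "run_mc", "braid_mc_profile"]


def braid_mc_profile(
    segment_nm: float = 15.0,
    persistence_length_nm: float = 50.0,
    effective_diameter_nm: float = 5.0,
    temperature_K: float = 293.0,
) -> tuple[UnitSystem, ForceFieldParams]:
    """Discrete worm-like-chain profile for braid angle sampling.

    Segments of ``segment_nm`` with bending stiffness Lp/segment, a thin
    excluded-volume diameter equal to the electrostatic effective
    diameter of DNA (~5 nm at 100 mM monovalent salt, screened charges
    folded in), and topology preserved by the Monte Carlo move filter
    rather than by the hard core -- the classic construction for
    braid/supercoil geometry sampling.
    """
    units = UnitSystem.coarse(segment_nm, temperature_K=temperature_K)
    params = ForceFieldParams.for_units(
        units,
        persistence_length_nm=persistence_length_nm,
        wca_sigma=effective_diameter_nm / segment_nm,
        charge=0.0,
        use_dh=False,
    )
    return units, params


@dataclass(frozen=True)
class MCMoveSet:
    """Relative weights and amplitudes of the Metropolis move set."""

    displacement_max: float = 0.35      # sigma
    crankshaft_max_angle: float = 1.2   # rad
    link_dz_max: float = 0.5            # sigma
    move_weights: tuple[float, float, float] = (0.5, 0.45, 0.05)

    def __post_init__(self) -> None:
        if min(self.displacement_max, self.crankshaft_max_angle,
               self.link_dz_max) <= 0:
            raise ValueError("move amplitudes must be positive")
        if min(self.move_weights) < 0 or sum(self.move_weights) <= 0:
            raise ValueError("move_weights must be normalizable")

    def normalized(self) -> tuple[float, float, float]:
        s = sum(self.move_weights)
        return tuple(w / s for w in self.move_weights)


def _run_kernel(pos, cid, n1, f_red, beta, params: ForceFieldParams,
                moves: MCMoveSet, n_sweeps, sample_every, n_burn,
                check_topology, seed, frames):
    w_disp, w_crank, w_link = moves.normalized()
    single_chain = n1 == pos.shape[0]
    if single_chain:
        # no partner chain: disable link move and topology bookkeeping
        tot = w_disp + w_crank
        w_disp, w_crank = w_disp / tot, w_crank / tot
        check_topology = False
    return _kernels.run_mc_kernel(
        pos, cid, n1, f_red, beta,
        params.k_fene, params.r0, params.k_bend,
        params.use_dh and params.charge != 0.0, params.dh_prefactor,
        params.screening_sigma, params.dh_cutoff_sigma,
        moves.displacement_max, moves.crankshaft_max_angle,
        moves.link_dz_max, w_disp, w_crank,
        n_sweeps, sample_every, n_burn, check_topology,
        int(seed) % (2**31 - 1), frames, params.wca_sigma**2,
    )


def mc_sweep(
    conf: Conformation,
    params: ForceFieldParams,
    moves: MCMoveSet,
    seed: int,
    f_red: float = 0.0,
    beta: float = 1.0,
    n_sweeps: int = 1,
    check_topology: bool = True,
) -> tuple[Conformation, dict]:
    """Run ``n_sweeps`` Metropolis sweeps in place on a copy of ``conf``.

    One sweep attempts one move per bead on average.  Returns the new
    conformation and acceptance statistics.
    """
    out = conf.copy()
    n1 = int(np.sum(out.chain_ids == 0))
    frames = np.empty((0, out.positions.shape[0], 3))
    n_acc, n_att, n_topo, _ = _run_kernel(
        out.positions, out.chain_ids, n1, f_red, beta, params, moves,
        n_sweeps, n_sweeps + 1, 0, check_topology, seed, frames,
    )
    stats = {
        "n_accepted": int(n_acc),
        "n_attempted": int(n_att),
        "acceptance": n_acc / max(1, n_att),
        "n_topology_rejects": int(n_topo),
    }
    return out, stats


def run_mc(
    system: BraidSystem,
    params: ForceFieldParams,
    n_sweeps: int,
    sample_every: int = 10,
    seed: int = 0,
    units: UnitSystem | None = None,
    equil_fraction: float = 0.1,
    moves: MCMoveSet | None = None,
    beta: float = 1.0,
    initial: Conformation | None = None,
    check_topology: bool = True,
) -> Trajectory:
    """Equilibrium MC trajectory of a braided tether pair.

    Decorrelated frames are stored every ``sample_every`` sweeps after a
    burn-in of ``equil_fraction * n_sweeps`` sweeps; the per-frame
    catenation number is verified against the imposed turn count, and an
    autocorrelation-based effective sample size of the extension series
    is recorded in the trajectory metadata.
    """
    if n_sweeps < 100 * sample_every:
        raise ValueError("n_sweeps must be >= 100 * sample_every")
    units = units or UnitSystem()
    moves = moves or MCMoveSet()
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

    n_burn = int(round(equil_fraction * n_sweeps))
    n_store = (n_sweeps - n_burn) // sample_every
    frames = np.empty((n_store, pos.shape[0], 3))
    n_acc, n_att, n_topo, n_filled = _run_kernel(
        pos, cid, n1, f_red, beta, params, moves, n_sweeps, sample_every,
        n_burn, check_topology, seed, frames,
    )
    frames = frames[:n_filled]
    traj = Trajectory(
        frames=frames,
        chain_ids=cid,
        sample_interval=float(sample_every),
        seed=int(seed),
        units=units,
        params=params,
        system=system,
        meta={
            "engine": "mc",
            "n_sweeps": n_sweeps,
            "n_burn": n_burn,
            "acceptance": n_acc / max(1, n_att),
            "n_topology_rejects": int(n_topo),
        },
    )
    traj.meta["ess_extension"] = effective_sample_size(traj.extension_nm())
    if check_topology:
        from .crossing import verify_topology

        verify_topology(traj, expected=system.n_turns)
    return traj
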