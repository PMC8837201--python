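"""Braided-tether system geometry and trajectory container.

Two DNA duplexes are anchored to a surface at points ``spacing_e`` apart
and to a magnet-held attachment assembly at the top.  Rotating the
assembly winds the tethers around each other; ``n_turns`` counts the
imposed DNA crossings (one crossing per half-turn of the attachment
pair, so odd values leave the attachment sides swapped in an X).
Positive values impose left-handed crossings.  The assembly is reduced
to two attachment points on a virtual rigid link that stay laterally
pinned while the tethers carry the applied force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .units import Conformation, ForceFieldParams, UnitSystem, bond_rest_length

__all__ = ["BraidSystem", "Trajectory", "BraidConstructionError",
           "build_initial_braid", "HELIX_RADIUS_SIGMA", "HELIX_PITCH_SIGMA"]

#: radius (sigma) of the interwound mid-section used by the builder
HELIX_RADIUS_SIGMA = 1.0
#: vertical rise (sigma) per imposed crossing (half-turn) at construction
HELIX_PITCH_SIGMA = 2.5


class BraidConstructionError(ValueError):
    """Requested braid geometry cannot be formed from the given tethers."""


@dataclass(frozen=True)
class BraidSystem:
    """Experimental geometry of a braided-tether assay (laboratory units)."""

    dna_bp: float
    spacing_e_nm: float
    force_pN: float
    n_turns: int = 0
    top_separation_nm: float | None = None

    def __post_init__(self) -> None:
        if self.spacing_e_nm <= 0:
            raise ValueError("spacing_e_nm must be positive")
        if self.force_pN < 0:
            raise ValueError("force_pN must be >= 0")
        if self.dna_bp < 30:
            raise ValueError("dna_bp too short to braid")

    @property
    def top_sep_nm(self) -> float:
        return (self.top_separation_nm
                if self.top_separation_nm is not None else self.spacing_e_nm)

    def contour_length_nm(self, nm_per_bp: float = 0.338) -> float:
        return self.dna_bp * nm_per_bp

    def n_beads_per_chain(self, units: UnitSystem) -> int:
        return units.n_beads(self.dna_bp)

    def to_dict(self) -> dict:
        return {
            "dna_bp": self.dna_bp,
            "spacing_e_nm": self.spacing_e_nm,
            "force_pN": self.force_pN,
            "n_turns": self.n_turns,
            "top_separation_nm": self.top_sep_nm,
        }


@dataclass
class Trajectory:
    """Stored frames of a braid simulation, positions in sigma units."""

    frames: np.ndarray              # (n_frames, n_beads, 3)
    chain_ids: np.ndarray
    sample_interval: float          # tau (BD) or sweeps (MC)
    seed: int
    units: UnitSystem
    params: ForceFieldParams
    system: BraidSystem | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("need at least one (n, 3) frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_chain0(self) -> int:
        return int(np.sum(self.chain_ids == 0))

    def extension_nm(self) -> np.ndarray:
        """Per-frame mean height of the two top attachment beads, nm."""
        n1 = self.n_chain0
        z = 0.5 * (self.frames[:, n1 - 1, 2] + self.frames[:, -1, 2])
        return z * self.units.sigma_nm

    def conformation(self, frame: int = -1) -> Conformation:
        return Conformation(self.frames[frame].copy(), self.chain_ids.copy())


#: azimuthal offset (rad) of the interwound section entry; keeps the
#: built legs out of a common vertical plane so projections are generic
_ENTRY_TWIST = 0.3


def _path_point(s, x_anchor, x_top, phi0, handedness, n_abs, rho, ell_s,
                ell_h, z1, h, H):
    """Point at arc length s along the built braid path of one chain.

    The interwound mid-section advances the azimuth by pi per imposed
    crossing, so odd crossing numbers exit on the opposite side."""
    if n_abs == 0:
        return np.array([x_anchor, 0.0, s])
    phi_in = phi0 + (_ENTRY_TWIST if phi0 > 0 else -_ENTRY_TWIST)
    phi_exit = phi_in + handedness * math.pi * n_abs
    if s <= ell_s:
        t = s / ell_s
        start = np.array([x_anchor, 0.0, 0.0])
        end = np.array([rho * math.cos(phi_in), rho * math.sin(phi_in), z1])
        return start + t * (end - start)
    if s <= ell_s + ell_h:
        t = (s - ell_s) / ell_h
        phi = phi_in + handedness * math.pi * n_abs * t
        return np.array([rho * math.cos(phi), rho * math.sin(phi), z1 + h * t])
    t = (s - ell_s - ell_h) / ell_s
    start = np.array(
        [rho * math.cos(phi_exit), rho * math.sin(phi_exit), z1 + h]
    )
    end = np.array([x_top, 0.0, H])
    return start + t * (end - start)


def _equal_chord_spacing(point, L_tot: float, N: int) -> np.ndarray:
    """Place N beads along ``point(s)`` with (near-)equal chord lengths.

    A kinked path makes chords shorter than arcs; equalising chords keeps
    every starting bond near its rest length.  Iterates arc positions a
    few times, rescaling increments toward uniform chord length.
    """
    s = np.linspace(0.0, L_tot, N)
    for _ in range(12):
        pts = np.array([point(x) for x in s])
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        target = chords.mean()
        # adjust arc increments proportionally to chord deficit
        ds = np.diff(s) * np.clip(target / np.maximum(chords, 1e-12), 0.5, 2.0)
        s = np.concatenate([[0.0], np.cumsum(ds)])
        s *= L_tot / s[-1]
        if np.max(np.abs(chords - target)) < 1e-3 * target:
            break
    return np.array([point(x) for x in s])


def equilibrium_extension_estimate(
    system: BraidSystem,
    units: UnitSystem,
    params: "ForceFieldParams",
) -> float:
    """Chord-model estimate of the equilibrium extension, sigma units.

    Worm-like-chain contraction at the per-tether force (total bead
    force shared by the two tethers) applied to the taut-crossing
    geometry; used to pre-shrink the built conformation so the slow
    extension mode starts near equilibrium.
    """
    from .mechanics import wlc_relative_extension

    lp_nm = params.k_bend * units.sigma_nm
    z_rel = wlc_relative_extension(
        max(system.force_pN / 2.0, 1e-3), lp_nm, units.kT_pNnm
    )
    N = system.n_beads_per_chain(units)
    contour = (N - 1) * bond_rest_length(params)
    ell = z_rel * contour
    if system.n_turns == 0:
        return ell
    e = units.length_to_reduced(system.spacing_e_nm)
    if ell <= e * 1.02:
        return 0.9 * ell
    return math.sqrt(ell * ell - e * e)


def _inject_slack(pos, N, target_H, r_b, z1, h, n_abs, H):
    """Shrink the leg height so the build starts near the equilibrium
    extension, restoring bond lengths with an alternating y zigzag
    (local, fast-relaxing slack).  The interwound mid-section keeps its
    built geometry and rides at the compressed height."""
    legs_H = H - h
    if legs_H <= 0 or target_H >= H:
        return H
    # compression floor: below ~0.62 the zigzag brings next-nearest
    # beads inside the WCA core; deeper contraction is left to the run
    s = max(target_H - h, 0.62 * legs_H) / legs_H
    for c in range(2):
        chain = pos[c * N:(c + 1) * N]
        z_old = chain[:, 2].copy()
        below = z_old <= z1
        mid = (z_old > z1) & (z_old < z1 + h)
        above = z_old >= z1 + h
        chain[below, 2] = z_old[below] * s
        chain[mid, 2] = z1 * s + (z_old[mid] - z1)
        chain[above, 2] = z1 * s + h + (z_old[above] - z1 - h) * s
        for k in range(1, N - 1, 2):
            if not (below[k] or above[k]):
                continue
            d = chain[k] - chain[k - 1]
            need = r_b * r_b - d[0] * d[0] - d[2] * d[2]
            if need > 0:
                chain[k, 1] += math.sqrt(need)
        # the final bond is missed when N-2 is even; restore it along x
        # (orthogonal to the zigzag, leaves the previous bond intact)
        k = N - 2
        if k % 2 == 0 and (below[k] or above[k]):
            d = chain[k + 1] - chain[k]
            need = r_b * r_b - d[1] * d[1] - d[2] * d[2]
            if need > d[0] * d[0]:
                chain[k, 0] += math.sqrt(need) - abs(d[0])
    return legs_H * s + h


def build_initial_braid(
    system: BraidSystem,
    units: UnitSystem,
    params: ForceFieldParams | None = None,
    seed: int | None = None,
    extension_sigma: float | None = None,
) -> Conformation:
    """Deterministic interwound starting conformation.

    Both chains run from their surface anchor through an interwound
    helical mid-section of ``|n_turns|`` full turns back to the
    attachment point directly above their own anchor.  All bonds start
    at the FENE+WCA rest length; no non-bonded pair is closer than
    2 * HELIX_RADIUS_SIGMA.  ``seed`` is accepted for API symmetry (the
    construction itself is deterministic).
    """
    params = params or ForceFieldParams()
    N = system.n_beads_per_chain(units)
    r_b = bond_rest_length(params)
    L_tot = (N - 1) * r_b
    e = units.length_to_reduced(system.spacing_e_nm)
    n = system.n_turns
    n_abs = abs(n)
    rho = HELIX_RADIUS_SIGMA

    if n_abs == 0:
        H = L_tot
        z1 = h = ell_s = ell_h = 0.0
        handedness = 0
    else:
        # positive crossings are left-handed: azimuth decreases with height
        handedness = -1 if n > 0 else 1
        h = n_abs * HELIX_PITCH_SIGMA
        ell_h = n_abs * math.sqrt(
            (math.pi * rho) ** 2 + HELIX_PITCH_SIGMA**2
        )
        half = 0.5 * (L_tot - ell_h)
        dx = abs(e / 2.0 - rho)
        if half <= dx or L_tot <= ell_h:
            raise BraidConstructionError(
                f"{n} crossings not formable: tether contour {L_tot:.1f} "
                f"sigma, anchor spacing {e:.1f} sigma"
            )
        z1 = math.sqrt(half * half - dx * dx)
        ell_s = math.sqrt(dx * dx + z1 * z1)
        H = 2.0 * z1 + h

    pos = np.empty((2 * N, 3))
    anchors = np.array([[-e / 2.0, 0.0, 0.0], [e / 2.0, 0.0, 0.0]])
    for c, (x_a, phi0) in enumerate(((-e / 2.0, math.pi), (e / 2.0, 0.0))):
        x_top = x_a if n_abs % 2 == 0 else -x_a
        if n_abs % 2 == 1:
            # odd crossing counts put a top attachment directly above the
            # other chain's surface anchor; nudge it outward so the
            # projected geometry is generic (mirror-symmetric in +-x)
            x_top += math.copysign(1.0, x_top)

        def point(s, x_a=x_a, x_top=x_top, phi0=phi0):
            return _path_point(
                s, x_a, x_top, phi0, handedness, n_abs, rho, ell_s, ell_h,
                z1, h, H
            )

        # march along the path placing beads at equal chord length, so
        # no bond starts compressed at the leg/helix junctions
        chord = _equal_chord_spacing(point, L_tot, N)
        for k in range(N):
            pos[c * N + k] = chord[k]
    if extension_sigma is not None and extension_sigma < H:
        H = _inject_slack(pos, N, extension_sigma, r_b, z1, h, n_abs, H)

    cid = np.repeat([0, 1], N)
    top = anchors.copy()
    if n_abs % 2 == 1:
        top = top[::-1].copy()  # odd crossing count swaps attachment sides
        top[:, 0] += np.sign(top[:, 0])  # same outward nudge as the paths
    top[:, 2] = H
    return Conformation(pos, cid, anchor_bottom=anchors, anchor_top=top)


def effective_sample_size(series: np.ndarray) -> float:
    """ESS from the integrated autocorrelation time of a scalar series."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    # FFT autocorrelation, sum with the standard adaptive cutoff
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real / (var * n)
    tau = 1.0
    for k in range(1, n):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return float(max(1.0, n / tau))
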