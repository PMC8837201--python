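"""Analytic and semi-analytic DNA tether mechanics.

Covers the worm-like-chain force-extension of the tethers, the
geometric braid-extension model used to calibrate braided tethers
(length and anchor spacing from the extension-vs-turns curve), mean
crossing angles of braids and plectonemic supercoils as a function of
force, the plectoneme extension change per magnet turn (which sets the
~100 nm amplitude of a single strand-passage step at 0.4 pN), and
supercoiling "hat" calibration curves.

Conventions: one braid crossing = one imposed crossing (half-turn of
the attachment pair); a supercoil strand-passage event changes the
linking number by 2.  Positive (left-handed) crossings have acute mean
angles; negative are the supplement.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.optimize import brentq, curve_fit, minimize

from .units import KB_PN_NM

__all__ = [
    "TetherGeometry",
    "BucklingError",
    "wlc_relative_extension",
    "braid_extension",
    "calibrate_braid",
    "mean_braid_angle",
    "mean_supercoil_angle",
    "plectoneme_slope",
    "supercoil_hat_curve",
]

BJERRUM_NM = 0.715
#: effective DNA line charge (e/nm) entering the screened strand-strand
#: repulsion of the superhelix model; far-field matched value at ~0.1 M
EFFECTIVE_CHARGE_PER_NM = 8.0
#: hard lower bound on the superhelix radius (hydration + hard core)
MIN_SUPERHELIX_RADIUS_NM = 1.2


class BucklingError(ValueError):
    """Geometry outside the validity of the mechanical model."""


@dataclass(frozen=True)
class TetherGeometry:
    """Single- or double-tether mechanics parameters (laboratory units).

    ``force_pN`` is the force carried by ONE tether (a braid's total
    bead force is shared between its two tethers).
    """

    contour_length_nm: float
    spacing_e_nm: float = 0.0
    force_pN: float = 0.5
    salt_mM: float = 100.0
    persistence_length_nm: float = 50.0
    temperature_K: float = 293.0

    def __post_init__(self) -> None:
        if self.contour_length_nm <= 0 or self.force_pN < 0:
            raise ValueError("contour length and force must be positive")
        if self.spacing_e_nm < 0:
            raise ValueError("spacing must be >= 0")
        if self.spacing_e_nm >= 2.0 * self.contour_length_nm:
            raise ValueError("spacing exceeds reachable tether span")

    @property
    def kT_pNnm(self) -> float:
        return KB_PN_NM * self.temperature_K

    @property
    def debye_nm(self) -> float:
        return 0.305 / math.sqrt(self.salt_mM / 1000.0)


def wlc_relative_extension(force_pN: float, persistence_length_nm: float = 50.0,
                           kT_pNnm: float = 4.04) -> float:
    """Relative extension z/L of a worm-like chain at the given force.

    Uses the Marko-Siggia interpolation formula
    F Lp / kT = z/L + 1/(4 (1 - z/L)^2) - 1/4, inverted numerically.
    Accuracy relative to the exact WLC is a few percent, which is ample
    for calibration-scale work (tolerance-tested, not bit-specified).
    """
    if force_pN <= 0:
        return 0.0
    fl = force_pN * persistence_length_nm / kT_pNnm

    def resid(x):
        return x + 0.25 / (1.0 - x) ** 2 - 0.25 - fl

    return brentq(resid, 0.0, 1.0 - 1e-9, xtol=1e-12)


# ---------------------------------------------------------------------------
# braid geometry
# ---------------------------------------------------------------------------

def _braid_extension_scalar(n, L, e, z_rel):
    ell = z_rel * L           # thermally contracted tether length
    if abs(n) < 0.5:
        return ell
    if ell <= e:
        raise BucklingError("tethers shorter than anchor spacing")
    z1 = math.sqrt(ell * ell - e * e)
    n_abs = abs(n)
    if n_abs <= 1:
        return z1
    return z1 / math.sqrt(1.0 + (math.pi * e * (n_abs - 1) / (2.0 * z1)) ** 2)


def braid_extension(n_turns, g: TetherGeometry,
                    check_buckling: bool = True) -> np.ndarray | float:
    """Extension (nm) of a braid with ``n_turns`` imposed crossings.

    n = 0 is the worm-like-chain extension of the parallel tethers; the
    first crossing drops the extension to sqrt((zL)^2 - e^2); further
    crossings follow the helical braid model
    z(n) = z1 / sqrt(1 + (pi e (|n|-1) / (2 z1))^2), symmetric in +-n.
    Buckling (the switch to supercoiled-braid behaviour) is flagged
    when the model extension falls below 25% of the one-crossing value.
    """
    z_rel = wlc_relative_extension(
        g.force_pN, g.persistence_length_nm, g.kT_pNnm
    )
    n_arr = np.atleast_1d(np.asarray(n_turns, dtype=float))
    out = np.array([
        _braid_extension_scalar(n, g.contour_length_nm, g.spacing_e_nm, z_rel)
        for n in n_arr
    ])
    if check_buckling and np.any(np.abs(n_arr) >= 1):
        z1 = _braid_extension_scalar(1, g.contour_length_nm,
                                     g.spacing_e_nm, z_rel)
        if np.any(out[np.abs(n_arr) >= 1] < 0.25 * z1):
            raise BucklingError(
                "braid beyond the geometric model's buckling threshold"
            )
    return out if np.ndim(n_turns) else float(out[0])


def calibrate_braid(turn_extension_pairs, g0: TetherGeometry | None = None):
    """Fit (contour length, anchor spacing) to an extension-vs-turns curve.

    Needs >= 5 points including n = 0 (otherwise the contour length is
    unidentifiable) and at least one |n| >= 2 point.  Returns
    ``(contour_length_nm, spacing_e_nm, fit)`` where ``fit`` carries
    standard errors and residuals.
    """
    pairs = np.asarray(turn_extension_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 5:
        raise ValueError("need >= 5 (turns, extension) pairs")
    n, z = pairs[:, 0], pairs[:, 1]
    if not np.any(n == 0):
        raise ValueError("calibration requires an n=0 point "
                         "(contour length unidentifiable)")
    if not np.any(np.abs(n) >= 2):
        raise ValueError("calibration requires |n| >= 2 points")
    g0 = g0 or TetherGeometry(contour_length_nm=float(z.max() * 1.3),
                              spacing_e_nm=float(z.max()) * 0.5,
                              force_pN=1.0)

    def model(nn, L, e):
        g = TetherGeometry(
            contour_length_nm=L, spacing_e_nm=e, force_pN=g0.force_pN,
            salt_mM=g0.salt_mM,
            persistence_length_nm=g0.persistence_length_nm,
            temperature_K=g0.temperature_K,
        )
        return braid_extension(nn, g, check_buckling=False)

    p0 = [g0.contour_length_nm, g0.spacing_e_nm]
    try:
        popt, pcov = curve_fit(model, n, z, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"braid calibration did not converge: {err}")
    resid = z - model(n, *popt)
    # jackknife standard errors: robust to the strongly heteroscedastic
    # noise of extension-vs-turns data
    jk = []
    for i in range(len(n)):
        mask = np.arange(len(n)) != i
        if not np.any(n[mask] == 0) or not np.any(np.abs(n[mask]) >= 2):
            continue
        try:
            pj, _ = curve_fit(model, n[mask], z[mask], p0=popt,
                              maxfev=20000)
            jk.append(pj)
        except RuntimeError:
            continue
    if len(jk) >= 3:
        jk = np.asarray(jk)
        m = len(jk)
        se = np.sqrt((m - 1) / m * np.sum((jk - jk.mean(0)) ** 2, axis=0))
    else:
        se = np.sqrt(np.diag(pcov))
    fit = {
        "contour_length_nm": float(popt[0]),
        "spacing_e_nm": float(abs(popt[1])),
        "se_contour_nm": float(se[0]),
        "se_spacing_nm": float(se[1]),
        "residuals_nm": resid,
        "rms_nm": float(np.sqrt(np.mean(resid**2))),
    }
    return float(popt[0]), float(abs(popt[1])), fit


def _chord_angle_3d(w: float, z: float) -> float:
    """3-D angle (deg) between the two crossing chords of a taut braid."""
    return math.degrees(2.0 * math.atan2(w, z))


def mean_braid_angle(
    g: TetherGeometry,
    n_turns: int = 1,
    chirality: int = +1,
    mode: str = "analytic",
    n_fluct_samples: int = 20000,
    seed: int = 2024,
    mc_kwargs: dict | None = None,
) -> float:
    """Mean DNA-crossing angle (deg) of a braid at the given force.

    ``analytic`` mode evaluates a Gaussian tangent-fluctuation model on
    the taut-chord geometry: the two strands cross along chords with
    in-plane half-spans (w/2, z/2); each tangent is perturbed by
    transverse Gaussian fluctuations of variance kT/(F xi) with
    xi = sqrt(kT Lp / F) the tension correlation length, and the
    chirality-signed juxtaposition angle is averaged.  The model
    reproduces the acute-for-positive convention, the supplement
    identity, and the approach to 90 degrees as the imposed geometry
    vanishes.  ``simulate`` mode runs the Monte Carlo engine instead.
    """
    if chirality not in (+1, -1):
        raise ValueError("chirality must be +1 or -1")
    if chirality < 0:
        # supplement identity holds exactly by construction
        return 180.0 - mean_braid_angle(
            g, n_turns, +1, mode, n_fluct_samples, seed, mc_kwargs
        )
    if mode == "simulate":
        from .crossing import angle_distribution
        from .mc import run_mc
        from .system import BraidSystem
        from .units import ForceFieldParams, UnitSystem

        kw = dict(n_sweeps=4000, sample_every=5, seed=seed)
        kw.update(mc_kwargs or {})
        units = UnitSystem.coarse(5.0)
        params = ForceFieldParams.for_units(
            units, persistence_length_nm=g.persistence_length_nm
        )
        system = BraidSystem(
            dna_bp=g.contour_length_nm / 0.338,
            spacing_e_nm=g.spacing_e_nm,
            force_pN=2.0 * g.force_pN,   # total bead force
            n_turns=chirality * abs(n_turns),
        )
        traj = run_mc(system, params, units=units, **kw)
        return angle_distribution(traj, min_frames=50).mean_deg()

    z_rel = wlc_relative_extension(
        g.force_pN, g.persistence_length_nm, g.kT_pNnm
    )
    ell = z_rel * g.contour_length_nm
    z_n = braid_extension(n_turns, g)
    w = math.sqrt(max(ell * ell - z_n * z_n, 0.0))
    # per-crossing chord geometry: winding shared between |n| crossings
    w_c = w / max(1, abs(n_turns))
    z_c = z_n / max(1, abs(n_turns))
    # angular fluctuation of the leg-averaged duplex axis: transverse
    # wander of a tensioned chain over half a leg, kT/(F * l_leg)
    l_leg = max(ell / 2.0, 1e-6)
    s = math.sqrt(g.kT_pNnm / (g.force_pN * l_leg))
    rng = np.random.default_rng(seed)
    u0 = np.array([w_c / 2.0, 0.0, z_c / 2.0])
    v0 = np.array([-w_c / 2.0, 0.0, z_c / 2.0])
    u0 /= np.linalg.norm(u0)
    v0 /= np.linalg.norm(v0)
    u = u0 + s * rng.standard_normal((n_fluct_samples, 3))
    v = v0 + s * rng.standard_normal((n_fluct_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cross = np.cross(u, v)
    # juxtaposition axis: the geometric contact normal oriented by the
    # crossing handedness, with the same fluctuation scale as the
    # tangents; when the chords degenerate (parallel strands) the axis
    # direction randomises and the mean angle relaxes to 90 degrees
    axis0 = chirality * np.cross(u0, v0)
    axis = axis0[None, :] + s * rng.standard_normal((n_fluct_samples, 3))
    norm = np.linalg.norm(axis, axis=1)
    ok = norm > 1e-9
    axis = axis[ok] / norm[ok, None]
    sin_cw = -np.einsum("ij,ij->i", cross[ok], axis)
    cos_cw = np.einsum("ij,ij->i", u[ok], v[ok])
    ang = np.degrees(np.arctan2(sin_cw, cos_cw)) % 360.0
    mean = float(np.mean(ang % 180.0))
    # positive (left-handed) crossings are reported as the acute branch
    return min(mean, 180.0 - mean)


# ---------------------------------------------------------------------------
# plectoneme superhelix model
# ---------------------------------------------------------------------------

def _es_per_nm(d_nm: float, g: TetherGeometry) -> float:
    """Screened electrostatic repulsion per nm between the two strands
    of a superhelix at axis separation d (Ubbink-Odijk form), in kT/nm."""
    lam = g.debye_nm
    nu2 = EFFECTIVE_CHARGE_PER_NM**2
    return (0.5 * BJERRUM_NM * nu2
            * math.sqrt(2.0 * math.pi * lam / max(d_nm, 1e-6))
            * math.exp(-d_nm / lam))


def _plectoneme_optimum(g: TetherGeometry):
    """Minimize the superhelix free energy per writhe turn.

    Energy per unit plectoneme contour: bending (kT Lp/2) kappa^2 with
    kappa = sin^2(gamma)/R, screened electrostatics at strand distance
    2R, and the work F z_rel of removing contour from the stretched
    tail.  The contour per writhe turn is 2 pi R/(sin g cos g).
    Returns (R_nm, gamma_rad, contour_per_turn_nm).
    """
    kT = g.kT_pNnm
    A = kT * g.persistence_length_nm
    z_rel = wlc_relative_extension(
        g.force_pN, g.persistence_length_nm, kT
    )
    f_tail = g.force_pN * z_rel / kT   # kT/nm

    def per_turn(x):
        R, gam = x
        if R < MIN_SUPERHELIX_RADIUS_NM or not (0.05 < gam < 1.45):
            return 1e9
        s, c = math.sin(gam), math.cos(gam)
        ell_turn = 2.0 * math.pi * R / (s * c)
        f = (0.5 * A / kT * (s * s / R) ** 2
             + _es_per_nm(2.0 * R, g) + f_tail)
        return ell_turn * f

    best = None
    for R0 in (2.0, 4.0, 8.0, 15.0):
        for g0 in (0.5, 0.8, 1.1):
            res = minimize(per_turn, [R0, g0], method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
    R, gam = best.x
    if not (MIN_SUPERHELIX_RADIUS_NM <= R <= 60.0) or not (0.05 < gam < 1.45):
        raise BucklingError("no stable superhelix at this force")
    s, c = math.sin(gam), math.cos(gam)
    return float(R), float(gam), float(2.0 * math.pi * R / (s * c))


def mean_supercoil_angle(g: TetherGeometry, chirality: int = +1) -> float:
    """Mean plectoneme crossing angle (deg) at the given force.

    From the variational ideal-superhelix model: the two antiparallel
    strands at pitch angle gamma cross at 180 - 2 gamma degrees in 3-D;
    positive supercoils are reported acute, negative as the supplement.
    """
    if chirality not in (+1, -1):
        raise ValueError("chirality must be +1 or -1")
    _, gam, _ = _plectoneme_optimum(g)
    theta = 180.0 - 2.0 * math.degrees(gam)
    alpha_pos = min(theta, 180.0 - theta)
    return alpha_pos if chirality > 0 else 180.0 - alpha_pos


def plectoneme_slope(g: TetherGeometry) -> float:
    """Extension change per magnet turn in the plectonemic regime (nm).

    One strand-passage event (Delta Lk = 2) therefore releases twice
    this value -- ~100 nm at 0.4 pN, 100 mM salt, Lp = 50 nm.
    Intensive: independent of total DNA length.
    """
    kT = g.kT_pNnm
    z_rel = wlc_relative_extension(g.force_pN, g.persistence_length_nm, kT)
    _, _, ell_turn = _plectoneme_optimum(g)
    return float(z_rel * ell_turn)


def _buckling_turns(g: TetherGeometry) -> float:
    """Magnet turns at the onset of plectoneme formation."""
    kT = g.kT_pNnm
    torque_b = math.sqrt(2.0 * kT * g.persistence_length_nm * g.force_pN)
    C_nm = 100.0  # twist persistence length
    return (torque_b * g.contour_length_nm
            / (2.0 * math.pi * C_nm * kT))


MELTING_FORCE_PN = 0.7  # above this, negative turns melt instead of writhe


def supercoil_hat_curve(turns, g: TetherGeometry) -> np.ndarray:
    """Extension vs magnet turns for a torsionally constrained tether.

    Symmetric hat at low force; above ~0.7 pN negative rotation drives
    local melting rather than negative writhe, so the extension stays
    at the torsionally relaxed value for all negative turns.
    """
    turns = np.atleast_1d(np.asarray(turns, dtype=float))
    kT = g.kT_pNnm
    z_rel = wlc_relative_extension(g.force_pN, g.persistence_length_nm, kT)
    z0 = z_rel * g.contour_length_nm
    n_b = _buckling_turns(g)
    slope = plectoneme_slope(g)
    out = np.empty_like(turns)
    for i, n in enumerate(turns):
        if g.force_pN >= MELTING_FORCE_PN and n < 0:
            out[i] = z0
            continue
        a = abs(n)
        if a <= n_b:
            # small pre-buckling quadratic shortening (twist-bend coupling)
            out[i] = z0 * (1.0 - 0.01 * (a / max(n_b, 1e-9)) ** 2)
        else:
            out[i] = max(z0 * 0.99 - slope * (a - n_b), 0.0)
    return out if np.ndim(turns) else float(out[0])
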