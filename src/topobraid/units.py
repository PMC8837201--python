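"""Reduced units and the coarse-grained DNA force field.

The DNA is modelled as a charged bead-spring polymer in reduced
Lennard-Jones units: one bead of diameter ``sigma`` (~2.5 nm, ~7.4 bp)
carries a charge of -2.96 e, consecutive beads are bound by FENE springs,
chain stiffness enters through a cosine bending term, excluded volume is a
WCA potential and electrostatics a truncated Debye-Hueckel potential:

    U_total = U_FENE + U_BEND + U_WCA + U_DH

All energies are in units of kT, lengths in sigma.  Conversion to nm / pN
/ seconds happens only at I/O boundaries through :class:`UnitSystem`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "UnitSystem",
    "ForceFieldParams",
    "Conformation",
    "BondDomainError",
    "fene_energy",
    "bend_energy",
    "wca_energy",
    "dh_energy",
    "total_energy",
    "forces",
    "bond_rest_length",
    "WCA_CUTOFF",
]

#: WCA cutoff in units of the WCA diameter.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 0.0138


class BondDomainError(ValueError):
    """A FENE bond reached or exceeded its maximum extension R0."""


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and laboratory units.

    Parameters
    ----------
    sigma_nm:
        Length of one reduced unit in nm.  2.5 nm in the fine-grained
        model; coarse profiles use larger beads.
    bp_per_monomer:
        Base pairs represented by one bead (7.4 bp at sigma = 2.5 nm,
        rescaled proportionally for coarser beads).
    temperature_K:
        Absolute temperature.
    """

    sigma_nm: float = 2.5
    bp_per_monomer: float = 7.4
    temperature_K: float = 293.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.bp_per_monomer <= 0:
            raise ValueError("sigma_nm and bp_per_monomer must be positive")

    @property
    def kT_pNnm(self) -> float:
        """Thermal energy in pN nm."""
        return KB_PN_NM * self.temperature_K

    @property
    def nm_per_bp(self) -> float:
        return self.sigma_nm / self.bp_per_monomer

    def force_to_reduced(self, force_pN: float) -> float:
        return force_pN * self.sigma_nm / self.kT_pNnm

    def force_from_reduced(self, f_red: float) -> float:
        return f_red * self.kT_pNnm / self.sigma_nm

    def length_to_reduced(self, nm: float) -> float:
        return nm / self.sigma_nm

    def length_from_reduced(self, sig) :
        return np.asarray(sig) * self.sigma_nm

    def n_beads(self, dna_bp: float) -> int:
        """Number of beads representing a ``dna_bp`` base-pair tether."""
        return max(3, int(round(dna_bp / self.bp_per_monomer)))

    @classmethod
    def coarse(cls, sigma_nm: float, temperature_K: float = 293.0) -> "UnitSystem":
        """Coarser bead, keeping the 0.338 nm/bp rise of the 2.5 nm model."""
        return cls(
            sigma_nm=sigma_nm,
            bp_per_monomer=7.4 * sigma_nm / 2.5,
            temperature_K=temperature_K,
        )


# keys used by the flat text config round-trip
_CONFIG_KEYS = {
    "k_fene": "k_fene",
    "r0": "r0",
    "k_bend": "k_bend",
    "charge": "charge",
    "epsilon": "epsilon",
    "bjerrum_sigma": "bjerrum_sigma",
    "screening_sigma": "screening_sigma",
    "dh_cutoff_sigma": "dh_cutoff_sigma",
    "wca_sigma": "wca_sigma",
}


@dataclass(frozen=True)
class ForceFieldParams:
    """Reduced-unit constants of the coarse-grained DNA energy model.

    ``bjerrum_sigma`` and ``screening_sigma`` are kept independent because
    the Debye-Hueckel exponent admits two dimensional readings; defaults
    follow the Bjerrum length of water ((1/3.66) sigma ~ 0.68 nm) and the
    Debye length at 100 mM monovalent salt (0.96 nm ~ 0.384 sigma with
    sigma = 2.5 nm).
    """

    k_fene: float = 30.0          # kT / sigma^2
    r0: float = 1.6               # sigma
    k_bend: float = 20.0          # kT
    charge: float = -2.96         # elementary charges per bead
    epsilon: float = 1.6          # dimensionless dielectric factor
    bjerrum_sigma: float = 1.0 / 3.66
    screening_sigma: float = 0.384
    dh_cutoff_sigma: float = 6.0
    use_dh: bool = True
    wca_sigma: float = 1.0   # excluded-volume diameter of NON-bonded pairs

    def __post_init__(self) -> None:
        if self.k_fene <= 0:
            raise ValueError("k_fene must be positive")
        if not (1.0 < self.r0 < 2.0):
            raise ValueError("r0 must lie in (1, 2) sigma")
        if self.k_bend < 0:
            raise ValueError("k_bend must be >= 0")
        if self.dh_cutoff_sigma <= 0:
            raise ValueError("dh_cutoff_sigma must be positive")
        if self.wca_sigma <= 0:
            raise ValueError("wca_sigma must be positive")

    @property
    def dh_prefactor(self) -> float:
        """lb q^2 / eps, the DH energy at r = 1 sigma before screening."""
        return self.bjerrum_sigma * self.charge**2 / self.epsilon

    @classmethod
    def for_units(
        cls,
        units: UnitSystem,
        persistence_length_nm: float = 50.0,
        **overrides,
    ) -> "ForceFieldParams":
        """Parameters for a coarse bead size.

        Bending stiffness is rescaled so k_bend * b = Lp.  For beads much
        larger than the Debye length the screened electrostatics are
        subsumed into the WCA effective diameter and switched off.
        """
        kw = dict(
            k_bend=persistence_length_nm / units.sigma_nm,
            charge=-2.96 * units.bp_per_monomer / 7.4,
        )
        if units.sigma_nm > 4.0:
            kw["use_dh"] = False
        kw.update(overrides)
        return cls(**kw)

    # -- flat key=value config round trip ---------------------------------
    def to_config(self, units: UnitSystem) -> str:
        lines = []
        for key in _CONFIG_KEYS:
            lines.append(f"{key}={getattr(self, key)!r}")
        lines.append(f"use_dh={int(self.use_dh)}")
        lines.append(f"sigma_nm={units.sigma_nm!r}")
        lines.append(f"bp_per_monomer={units.bp_per_monomer!r}")
        lines.append(f"temperature_k={units.temperature_K!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> tuple["ForceFieldParams", UnitSystem]:
        vals: dict[str, float] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            vals[key.strip()] = float(val)
        unknown = set(vals) - set(_CONFIG_KEYS) - {
            "use_dh", "sigma_nm", "bp_per_monomer", "temperature_k"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        units = UnitSystem(
            sigma_nm=vals.pop("sigma_nm", 2.5),
            bp_per_monomer=vals.pop("bp_per_monomer", 7.4),
            temperature_K=vals.pop("temperature_k", 293.0),
        )
        use_dh = bool(vals.pop("use_dh", 1.0))
        return cls(use_dh=use_dh, **vals), units


@dataclass
class Conformation:
    """Bead positions of one or more anchored chains, in sigma units.

    ``positions`` has shape (n_beads, 3); ``chain_ids`` assigns each bead
    to a chain; beads of one chain are contiguous and ordered from the
    surface anchor (bottom) to the top attachment.
    """

    positions: np.ndarray
    chain_ids: np.ndarray
    anchor_bottom: np.ndarray | None = None   # (n_chains, 3)
    anchor_top: np.ndarray | None = None      # (n_chains, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if len(self.chain_ids) != len(self.positions):
            raise ValueError("chain_ids length mismatch")
        for cid in np.unique(self.chain_ids):
            if np.sum(self.chain_ids == cid) < 3:
                raise ValueError("each chain needs at least 3 monomers")

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_ids))

    def chain(self, cid: int) -> np.ndarray:
        return self.positions[self.chain_ids == cid]

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded bead index pairs."""
        idx = np.arange(len(self.positions) - 1)
        same = self.chain_ids[:-1] == self.chain_ids[1:]
        return np.column_stack([idx[same], idx[same] + 1])

    def angles(self) -> np.ndarray:
        """(n_angles, 3) array of consecutive bead triples within chains."""
        idx = np.arange(len(self.positions) - 2)
        same = (self.chain_ids[:-2] == self.chain_ids[1:-1]) & (
            self.chain_ids[1:-1] == self.chain_ids[2:]
        )
        return np.column_stack([idx[same], idx[same] + 1, idx[same] + 2])

    def copy(self) -> "Conformation":
        return Conformation(
            self.positions.copy(),
            self.chain_ids.copy(),
            None if self.anchor_bottom is None else self.anchor_bottom.copy(),
            None if self.anchor_top is None else self.anchor_top.copy(),
        )


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def fene_energy(r, p: ForceFieldParams):
    """FENE bond energy, kT.  Diverges as r -> R0; r >= R0 is a domain error."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be >= 0")
    if np.any(r >= p.r0):
        raise BondDomainError(f"bond length {float(np.max(r)):.4f} >= R0={p.r0}")
    return -0.5 * p.k_fene * p.r0**2 * np.log(1.0 - (r / p.r0) ** 2)


def bend_energy(theta, p: ForceFieldParams):
    """Bending energy K_BEND (1 + cos theta); theta = pi is collinear."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < -1e-12) | (theta > math.pi + 1e-12)):
        raise ValueError("theta must lie in [0, pi]")
    return p.k_bend * (1.0 + np.cos(theta))


def wca_energy(r, p: ForceFieldParams = None):
    """Purely repulsive truncated-shifted LJ; exactly zero beyond 2^(1/6)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be > 0")
    out = np.zeros_like(r)
    inside = r < WCA_CUTOFF
    sr6 = (1.0 / r[inside]) ** 6
    out[inside] = 4.0 * (sr6 * sr6 - sr6) + 1.0
    return out if out.ndim else float(out)


def dh_energy(r, qi, qj, p: ForceFieldParams):
    """Screened Coulomb (Debye-Hueckel) energy, zero at/beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be > 0")
    out = np.zeros_like(r)
    inside = r < p.dh_cutoff_sigma
    ri = r[inside]
    out[inside] = (
        p.bjerrum_sigma * qi * qj / (p.epsilon * ri) * np.exp(-ri / p.screening_sigma)
    )
    return out if out.ndim else float(out)


def bond_rest_length(p: ForceFieldParams) -> float:
    """Minimum of FENE + WCA along a bond (~0.961 sigma at defaults)."""
    from scipy.optimize import minimize_scalar

    def u(r):
        return float(fene_energy(r, p) + wca_energy(r))

    res = minimize_scalar(u, bounds=(0.5, p.r0 * 0.999), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# total energy and analytic forces (numpy reference implementation; the
# simulation engines use the compiled kernels in _kernels.py, which are
# cross-checked against these functions in the test suite)
# ---------------------------------------------------------------------------

def _pair_terms(c: Conformation, p: ForceFieldParams):
    n = len(c.positions)
    d = c.positions[:, None, :] - c.positions[None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    iu = np.triu_indices(n, k=1)
    bonded = np.zeros((n, n), dtype=bool)
    b = c.bonds()
    bonded[b[:, 0], b[:, 1]] = True
    bonded[b[:, 1], b[:, 0]] = True
    return r, iu, bonded


def total_energy(c: Conformation, p: ForceFieldParams) -> float:
    """Sum of bonded terms plus pairwise WCA (all pairs) and DH (non-bonded)."""
    b = c.bonds()
    rb = np.linalg.norm(c.positions[b[:, 1]] - c.positions[b[:, 0]], axis=1)
    e = float(np.sum(fene_energy(rb, p)))

    a = c.angles()
    if len(a):
        v1 = c.positions[a[:, 0]] - c.positions[a[:, 1]]
        v2 = c.positions[a[:, 2]] - c.positions[a[:, 1]]
        ct = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        e += float(np.sum(p.k_bend * (1.0 + np.clip(ct, -1.0, 1.0))))

    r, iu, bonded = _pair_terms(c, p)
    rij = r[iu]
    bmask = bonded[iu]
    safe = np.where(rij > 0, rij, 1.0)
    scaled = np.where(bmask, safe, safe / p.wca_sigma)
    e += float(np.sum(wca_energy(scaled, p)[rij > 0]))
    if p.use_dh and p.charge != 0.0:
        mask = ~bmask
        e += float(
            np.sum(dh_energy(rij[mask], p.charge, p.charge, p))
        )
    return e


def forces(c: Conformation, p: ForceFieldParams) -> np.ndarray:
    """Analytic -grad(U_total), kT/sigma, per bead."""
    pos = c.positions
    f = np.zeros_like(pos)

    # FENE
    b = c.bonds()
    dv = pos[b[:, 1]] - pos[b[:, 0]]
    r = np.linalg.norm(dv, axis=1)
    if np.any(r >= p.r0):
        raise BondDomainError("bond length >= R0")
    mag = p.k_fene / (1.0 - (r / p.r0) ** 2)  # dU/dr / r
    fv = mag[:, None] * dv
    np.add.at(f, b[:, 0], fv)
    np.add.at(f, b[:, 1], -fv)

    # bending: U = K (1 + cos theta), theta at middle bead j between
    # a = r_i - r_j and b = r_k - r_j
    a = c.angles()
    if len(a):
        va = pos[a[:, 0]] - pos[a[:, 1]]
        vb = pos[a[:, 2]] - pos[a[:, 1]]
        na = np.linalg.norm(va, axis=1)
        nb = np.linalg.norm(vb, axis=1)
        ct = np.sum(va * vb, axis=1) / (na * nb)
        # grad of cos(theta) wrt endpoints
        ga = (vb / nb[:, None] - ct[:, None] * va / na[:, None]) / na[:, None]
        gb = (va / na[:, None] - ct[:, None] * vb / nb[:, None]) / nb[:, None]
        np.add.at(f, a[:, 0], -p.k_bend * ga)
        np.add.at(f, a[:, 2], -p.k_bend * gb)
        np.add.at(f, a[:, 1], p.k_bend * (ga + gb))

    # pairwise WCA + DH
    rmat, iu, bonded = _pair_terms(c, p)
    ii, jj = iu
    dvp = pos[ii] - pos[jj]
    rp = rmat[iu]
    mag = np.zeros_like(rp)  # -dU/dr
    bmask = bonded[iu]
    sig = np.where(bmask, 1.0, p.wca_sigma)
    rs = rp / sig
    wmask = rs < WCA_CUTOFF
    sr6 = (1.0 / rs[wmask]) ** 6
    mag[wmask] += 24.0 * (2.0 * sr6 * sr6 - sr6) / rs[wmask] / sig[wmask]
    if p.use_dh and p.charge != 0.0:
        dmask = (rp < p.dh_cutoff_sigma) & (~bmask)
        rd = rp[dmask]
        A = p.dh_prefactor
        mag[dmask] += (
            A * np.exp(-rd / p.screening_sigma) * (1.0 / rd**2 + 1.0 / (p.screening_sigma * rd))
        )
    fv = (mag / rp)[:, None] * dvp
    np.add.at(f, ii, fv)
    np.add.at(f, jj, -fv)
    return f
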