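"""File formats, pipeline configuration and the analysis pipeline.

Formats are deliberately plain text: traces as TSV with ``#key=value``
header lines, angle distributions as CSV with ``#`` metadata,
trajectories as multi-frame XYZ (chain id, x, y, z in nm) with a JSON
sidecar, results as JSON.  An HDF5 trajectory container mirroring the
XYZ schema is available when h5py is installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .crossing import AngleDistribution
from .system import BraidSystem, Trajectory
from .traces import Trace
from .units import ForceFieldParams, UnitSystem

__all__ = [
    "SchemaError",
    "read_trace",
    "write_trace",
    "write_distribution",
    "read_distribution",
    "write_trajectory",
    "read_trajectory",
    "PipelineConfig",
    "run_pipeline",
]

REQUIRED_TRACE_KEYS = ("sample_rate_hz",)


class SchemaError(ValueError):
    """A required header key is missing or malformed."""


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"#sample_rate_hz={trace.sample_rate_hz!r}\n")
        for key, val in sorted(trace.metadata.items()):
            fh.write(f"#{key}={val!r}\n")
        fh.write("time_s\textension_nm\n")
        for t, x in zip(trace.time_s, trace.extension_nm):
            fh.write(f"{t:.9g}\t{x:.9g}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict = {}
    rows_t, rows_x = [], []
    header_seen = False
    with path.open("r", newline=None) as fh:   # newline=None: CRLF ok
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                try:
                    meta[key.strip()] = json.loads(val.replace("'", '"'))
                except json.JSONDecodeError:
                    meta[key.strip()] = val.strip().strip("'\"")
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            parts = line.split("\t")
            rows_t.append(float(parts[0]))
            rows_x.append(float(parts[1]))
    for key in REQUIRED_TRACE_KEYS:
        if key not in meta:
            raise SchemaError(f"trace file missing required key {key!r}")
    rate = float(meta.pop("sample_rate_hz"))
    return Trace(np.asarray(rows_t), np.asarray(rows_x), rate, meta)


# ---------------------------------------------------------------------------
# angle distributions
# ---------------------------------------------------------------------------

def write_distribution(dist: AngleDistribution, path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"#chirality={dist.chirality_label}\n")
        fh.write(f"#n_frames={dist.n_frames}\n")
        for key in ("threshold_nm", "engine", "fraction_no_juxtaposition"):
            if key in dist.meta:
                fh.write(f"#{key}={dist.meta[key]}\n")
        fh.write("angle_deg_bin_center,density,counts\n")
        for c, d, k in zip(dist.bin_centers_deg, dist.density, dist.counts):
            fh.write(f"{c:.6g},{d:.9g},{k}\n")


def read_distribution(path) -> AngleDistribution:
    path = Path(path)
    meta: dict = {}
    with path.open("r", newline=None) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    data = []
    label = ""
    n_frames = 0
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key == "chirality":
                label = val
            elif key == "n_frames":
                n_frames = int(val)
            else:
                meta[key] = val
        elif not line[0].isalpha():
            data.append([float(x) for x in line.split(",")])
    arr = np.asarray(data)
    centers = arr[:, 0]
    width = centers[1] - centers[0]
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    return AngleDistribution(
        bin_edges_deg=edges,
        density=arr[:, 1],
        counts=arr[:, 2].astype(np.int64),
        n_frames=n_frames,
        chirality_label=label,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, prefix, hdf5: bool = False) -> None:
    """XYZ frames (chain id, x, y, z in nm) plus a JSON metadata sidecar;
    ``hdf5=True`` additionally writes an HDF5 container."""
    prefix = Path(prefix)
    sigma = traj.units.sigma_nm
    with open(f"{prefix}.xyz", "w", newline="\n") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.frames.shape[1]}\n")
            fh.write(f"frame {f}\n")
            for cid, (x, y, z) in zip(traj.chain_ids, traj.frames[f]):
                fh.write(
                    f"{cid} {x * sigma:.6f} {y * sigma:.6f} {z * sigma:.6f}\n"
                )
    meta = {
        "seed": traj.seed,
        "sample_interval": traj.sample_interval,
        "units": asdict(traj.units),
        "params": asdict(traj.params),
        "system": traj.system.to_dict() if traj.system else None,
        "meta": {k: v for k, v in traj.meta.items()
                 if isinstance(v, (int, float, str, bool, type(None)))},
    }
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=1))
    if hdf5:
        import h5py

        with h5py.File(f"{prefix}.h5", "w") as h5:
            h5.create_dataset("frames_nm", data=traj.frames * sigma)
            h5.create_dataset("chain_ids", data=traj.chain_ids)
            h5.attrs["metadata"] = json.dumps(meta)


def read_trajectory(prefix) -> Trajectory:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    units = UnitSystem(**meta["units"])
    params = ForceFieldParams(**meta["params"])
    system = BraidSystem(**{k: v for k, v in (meta["system"] or {}).items()
                            if k != "top_separation_nm"}) \
        if meta["system"] else None
    frames, cid = [], []
    with open(f"{prefix}.xyz") as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        frame = np.empty((n, 3))
        ids = np.empty(n, dtype=np.int64)
        for k in range(n):
            parts = lines[i + 2 + k].split()
            ids[k] = int(parts[0])
            frame[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(frame / units.sigma_nm)
        cid = ids
        i += n + 2
    return Trajectory(
        frames=np.asarray(frames),
        chain_ids=cid,
        sample_interval=meta["sample_interval"],
        seed=meta["seed"],
        units=units,
        params=params,
        system=system,
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat, human-diffable configuration of the full analysis pipeline."""

    dna_bp: float = 3000.0
    spacing_e_nm: float = 624.0
    force_pN: float = 1.0
    sigma_nm: float = 5.0
    engine: str = "mc"               # mc | bd
    total_tau: float = 5e4           # bd duration
    sample_every_tau: float = 20.0
    n_sweeps: int = 20000            # mc duration
    sample_every_sweeps: int = 5
    threshold_nm: float = 10.0
    bin_deg: float = 2.0
    tau_L_s: float = 8.4
    tau_R_s: float = 43.8
    n_cycles: int = 200
    mirror_negative: bool = True     # derive P_R from P_L by mirroring
    seed: int = 1
    out_dir: str = "pipeline_out"

    def validate(self) -> None:
        if self.force_pN < 0:
            raise ValueError("force_pN must be >= 0")
        if self.engine not in ("bd", "mc"):
            raise ValueError("engine must be 'bd' or 'mc'")
        if min(self.tau_L_s, self.tau_R_s) <= 0:
            raise ValueError("time constants must be positive")

    def to_text(self) -> str:
        return "\n".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in fields(self)
        ) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise SchemaError(f"unknown config key {key!r}")
            val = val.strip().strip("'\"")
            if known[key] in ("int", int):
                kwargs[key] = int(val)
            elif known[key] in ("bool", bool):
                kwargs[key] = val in ("True", "true", "1")
            elif known[key] in ("str", str):
                kwargs[key] = val
            else:
                kwargs[key] = float(val)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, measure angle distributions, generate unlinking times,
    fit, and infer the preferred crossing angle; returns the manifest.

    Stage failures raise with the stage name; partial outputs persist in
    the output directory.
    """
    from .bd import run_bd
    from .crossing import angle_distribution, mirror_distribution
    from .kinetics import fit_exponential, infer_preferred_angle, tau_ratio
    from .mc import run_mc
    from .synth import gen_single_crossing_assay

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.engine == "mc":
        from .mc import braid_mc_profile

        units, params = braid_mc_profile(segment_nm=config.sigma_nm)
    else:
        units = UnitSystem.coarse(config.sigma_nm)
        params = ForceFieldParams.for_units(
            units, wca_sigma=min(1.0, 8.4 / config.sigma_nm)
        )
    stage = "simulate"
    try:
        results = {}
        dists = {}
        for sign, label in ((+1, "L"), (-1, "R")):
            if sign < 0 and config.mirror_negative:
                continue
            system = BraidSystem(
                dna_bp=config.dna_bp, spacing_e_nm=config.spacing_e_nm,
                force_pN=config.force_pN, n_turns=sign,
            )
            if config.engine == "bd":
                traj = run_bd(system, params, config.total_tau,
                              config.sample_every_tau,
                              seed=config.seed + (0 if sign > 0 else 1),
                              units=units)
            else:
                traj = run_mc(system, params, config.n_sweeps,
                              config.sample_every_sweeps,
                              seed=config.seed + (0 if sign > 0 else 1),
                              units=units)
            stage = "angles"
            dist = angle_distribution(traj, config.threshold_nm,
                                      config.bin_deg)
            dists[label] = dist
            write_distribution(dist, out / f"p_{label}.csv")
            stage = "simulate"
        if "R" not in dists:
            dists["R"] = mirror_distribution(dists["L"])
            write_distribution(dists["R"], out / "p_R.csv")

        stage = "kinetics"
        trace, truth = gen_single_crossing_assay(
            config.tau_L_s, config.tau_R_s, config.n_cycles,
            seed=config.seed + 7,
        )
        write_trace(trace, out / "single_crossing_trace.tsv")
        fit_L = fit_exponential(truth.extras["waits_L_s"])
        fit_R = fit_exponential(truth.extras["waits_R_s"])
        rho, se_rho = tau_ratio(fit_L, fit_R)

        stage = "infer"
        res = infer_preferred_angle(dists["L"], dists["R"], rho, se_rho,
                                    method=config.engine.upper(),
                                    geometry={
                                        "dna_bp": config.dna_bp,
                                        "spacing_e_nm": config.spacing_e_nm,
                                        "force_pN": config.force_pN,
                                    })
        results = {
            "alpha0_deg": res.alpha0_deg,
            "stat_err_deg": res.stat_err_deg,
            "syst_err_deg": res.syst_err_deg,
            "rho": rho,
            "se_rho": se_rho,
            "tau_L_s": fit_L.tau_s,
            "tau_R_s": fit_R.tau_s,
            "method": res.method,
            "geometry": res.geometry,
        }
        (out / "alpha0.json").write_text(json.dumps(results, indent=1))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    stage = "manifest"
    config_text = config.to_text()
    (out / "config.txt").write_text(config_text)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "results": results,
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
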