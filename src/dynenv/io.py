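"""File formats, configuration, and the end-to-end pipeline runner.

Formats are deliberately plain text:

* trajectories — extended XYZ (per-frame blocks with ``Lattice=...``,
  ``Properties=species:S:1:pos:R:3[:vel:R:3]`` and ``pbc=...`` comment
  fields) or long-format CSV (particle_id, frame, x, y[, z][, vx, vy, vz]);
* signal ensembles and labels — long-format CSV (series_id, frame,
  value...), with a comment header naming units and the producing stage;
* configuration — JSON; every pipeline run writes the resolved config
  next to its outputs so results are reproducible from the artifact
  directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DescriptorSeries, ParticleTrajectory, SignalEnsemble, combine
from . import synthetic
from .active_matter import AlignmentParams, d_min, phi
from .denoise import spatial_average
from .frustration import frustration_gap, self_combination_control
from .onion import delta_t_scan, default_grid
from .reduction import pca_series
from .soap import SoapParams, descriptor_series

logger = logging.getLogger("dynenv")


# ---------------------------------------------------------------------------
# extended XYZ

class XYZParseError(ValueError):
    """Malformed extended-XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_key_values(comment: str) -> dict[str, str]:
    out: dict[str, str] = {}
    i = 0
    while i < len(comment):
        eq = comment.find("=", i)
        if eq < 0:
            break
        key = comment[i:eq].strip().split()[-1] if comment[i:eq].strip() else ""
        j = eq + 1
        if j < len(comment) and comment[j] == '"':
            end = comment.find('"', j + 1)
            value = comment[j + 1:end]
            i = end + 1
        else:
            end = comment.find(" ", j)
            end = len(comment) if end < 0 else end
            value = comment[j:end]
            i = end + 1
        if key:
            out[key] = value
    return out


def write_xyz(traj: ParticleTrajectory, path: str | Path) -> None:
    """Write one extended-XYZ block per frame (3D trajectories)."""
    if traj.dim != 3:
        raise ValueError("extended XYZ output requires 3D trajectories")
    species = traj.species or ["X"] * traj.n_particles
    b = traj.box
    lattice = f"{b[0]} 0.0 0.0 0.0 {b[1]} 0.0 0.0 0.0 {b[2]}"
    pbc = " ".join("T" if p else "F" for p in traj.periodic)
    has_vel = traj.velocities is not None
    props = "species:S:1:pos:R:3" + (":vel:R:3" if has_vel else "")
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(f'Lattice="{lattice}" Properties={props} pbc="{pbc}" '
                     f"dt_sample={traj.dt_sample} frame={t}\n")
            for i in range(traj.n_particles):
                row = " ".join(f"{v:.10g}" for v in traj.positions[i, t])
                if has_vel:
                    row += " " + " ".join(f"{v:.10g}" for v in traj.velocities[i, t])
                fh.write(f"{species[i]} {row}\n")


def read_xyz(path: str | Path) -> ParticleTrajectory:
    """Read an extended-XYZ trajectory (fixed particle count across frames)."""
    lines = Path(path).read_text().splitlines()
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    species: list[str] = []
    box = np.ones(3)
    periodic = np.zeros(3, dtype=bool)
    dt_sample = 1.0
    ln = 0
    n_expected = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError("expected a particle count", ln + 1) from None
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise XYZParseError(
                f"inconsistent particle count ({n} != {n_expected})", ln + 1)
        if ln + 1 >= len(lines):
            raise XYZParseError("missing comment line", ln + 2)
        fields = _parse_key_values(lines[ln + 1])
        if "Lattice" in fields:
            cell = np.fromstring(fields["Lattice"], sep=" ")
            if cell.size != 9:
                raise XYZParseError("Lattice must hold 9 numbers", ln + 2)
            box = cell.reshape(3, 3).diagonal().copy()
        if "pbc" in fields:
            periodic = np.array([tok.upper().startswith("T")
                                 for tok in fields["pbc"].split()], dtype=bool)
        if "dt_sample" in fields:
            dt_sample = float(fields["dt_sample"])
        has_vel = "vel" in fields.get("Properties", "")
        pos = np.empty((n, 3))
        vel = np.empty((n, 3)) if has_vel else None
        for i in range(n):
            row = lines[ln + 2 + i].split()
            want = 7 if has_vel else 4
            if len(row) < want:
                raise XYZParseError(
                    f"expected {want} columns, got {len(row)}", ln + 3 + i)
            try:
                nums = [float(v) for v in row[1:want]]
            except ValueError:
                raise XYZParseError("non-numeric coordinate", ln + 3 + i) from None
            pos[i] = nums[:3]
            if has_vel:
                vel[i] = nums[3:6]
            if not frames_pos:
                species.append(row[0])
        frames_pos.append(pos)
        if has_vel:
            frames_vel.append(vel)
        ln += 2 + n
    if not frames_pos:
        raise XYZParseError("empty trajectory", 1)
    positions = np.stack(frames_pos, axis=1)
    velocities = np.stack(frames_vel, axis=1) if frames_vel else None
    return ParticleTrajectory(positions=positions, box=box, periodic=periodic,
                              dt_sample=dt_sample, velocities=velocities,
                              species=species)


# ---------------------------------------------------------------------------
# CSV trajectories and series

def write_trajectory_csv(traj: ParticleTrajectory, path: str | Path) -> None:
    cols = ["x", "y", "z"][: traj.dim]
    vcols = ["vx", "vy", "vz"][: traj.dim] if traj.velocities is not None else []
    rows = []
    for i in range(traj.n_particles):
        for t in range(traj.n_frames):
            row = [i, t, *traj.positions[i, t]]
            if vcols:
                row += list(traj.velocities[i, t])
            rows.append(row)
    pd.DataFrame(rows, columns=["particle_id", "frame", *cols, *vcols]).to_csv(
        path, index=False)


def read_trajectory_csv(path: str | Path, box: np.ndarray | None = None,
                        periodic: np.ndarray | None = None,
                        dt_sample: float = 1.0) -> ParticleTrajectory:
    """Read (particle_id, frame, x, y[, z][, vx, vy, vz]) tracks; the box
    defaults to the tight bounding box of the data, open boundaries."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    vcols = [c for c in ("vx", "vy", "vz") if c in df.columns]
    pids = np.sort(df["particle_id"].unique())
    frames = np.sort(df["frame"].unique())
    n, t, dim = len(pids), len(frames), len(cols)
    pos = np.full((n, t, dim), np.nan)
    vel = np.full((n, t, dim), np.nan) if vcols else None
    pi = {p: i for i, p in enumerate(pids)}
    fi = {f: i for i, f in enumerate(frames)}
    for _, row in df.iterrows():
        i, j = pi[row["particle_id"]], fi[row["frame"]]
        pos[i, j] = [row[c] for c in cols]
        if vcols:
            vel[i, j] = [row[c] for c in vcols]
    if np.isnan(pos).any():
        raise ValueError("missing (particle, frame) combinations in tracks CSV")
    if box is None:
        box = pos.reshape(-1, dim).max(axis=0) - pos.reshape(-1, dim).min(axis=0)
        box = np.where(box > 0, box * 1.001, 1.0)
    if periodic is None:
        periodic = np.zeros(dim, dtype=bool)
    return ParticleTrajectory(positions=pos, box=np.asarray(box, dtype=float),
                              periodic=np.asarray(periodic, dtype=bool),
                              dt_sample=dt_sample, velocities=vel)


def write_ensemble_csv(ens: SignalEnsemble, path: str | Path, stage: str = "") -> None:
    n, t = ens.n_series, ens.n_frames
    d = ens.n_dims
    vals = ens.values.reshape(n, t, d)
    cols = ["value"] if d == 1 else [f"value_{j}" for j in range(d)]
    idx = np.indices((n, t))
    df = pd.DataFrame({"series_id": idx[0].ravel(), "frame": idx[1].ravel()})
    for j, c in enumerate(cols):
        df[c] = vals[:, :, j].ravel()
    with open(path, "w") as fh:
        fh.write(f"# dynenv signal ensemble; name={ens.name}; stage={stage or 'unknown'}; "
                 f"frame unit=frames; dt_sample={ens.dt_sample} time-units/frame\n")
        df.to_csv(fh, index=False)


def read_ensemble_csv(path: str | Path) -> SignalEnsemble:
    dt_sample, name = 1.0, Path(path).stem
    with open(path) as fh:
        first = fh.readline()
    header = first.startswith("#")
    if header:
        for token in first[1:].split(";"):
            token = token.strip()
            if token.startswith("dt_sample="):
                dt_sample = float(token.split("=", 1)[1].split()[0])
            elif token.startswith("name="):
                name = token.split("=", 1)[1]
    df = pd.read_csv(path, comment="#")
    sids = np.sort(df["series_id"].unique())
    frames = np.sort(df["frame"].unique())
    cols = [c for c in df.columns if c.startswith("value")]
    n, t, d = len(sids), len(frames), len(cols)
    vals = np.full((n, t, d), np.nan)
    si = {s: i for i, s in enumerate(sids)}
    fi = {f: i for i, f in enumerate(frames)}
    vals[[si[s] for s in df["series_id"]], [fi[f] for f in df["frame"]]] = df[cols].values
    if d == 1:
        vals = vals[:, :, 0]
    return SignalEnsemble(values=vals, dt_sample=dt_sample, name=name)


def write_labels_csv(labels: np.ndarray, path: str | Path, stage: str = "") -> None:
    n, t = labels.shape
    idx = np.indices((n, t))
    df = pd.DataFrame({"series_id": idx[0].ravel(), "frame": idx[1].ravel(),
                       "label": labels.ravel()})
    with open(path, "w") as fh:
        fh.write(f"# dynenv labels; stage={stage or 'unknown'}; -1=ENV0; frame unit=frames\n")
        df.to_csv(fh, index=False)


def write_scan_csv(scan, path: str | Path, stage: str = "") -> None:
    df = pd.DataFrame({"delta_t_frames": scan.delta_t,
                       "delta_t_time": scan.delta_t_time,
                       "n_states": scan.n_states,
                       "env0_fraction": scan.env0_fraction})
    with open(path, "w") as fh:
        fh.write(f"# dynenv delta-t scan; stage={stage or 'unknown'}; "
                 f"delta_t_time unit=dt_sample*frames\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration and runner

@dataclass
class PipelineConfig:
    """Resolved parameters of one full analysis run.

    ``generate`` selects the synthetic input ("two-phase", "wave",
    "ensemble" or "" to read ``input_path``); descriptor/denoise/reduce/
    onion stages run in the order of the standard workflow:
    descriptor -> spatial denoising -> PCA or component selection ->
    Δt scan (univariate and optionally bivariate) -> frustration gap.
    """

    seed: int = 0
    generate: str = "two-phase"
    generate_kwargs: dict = field(default_factory=dict)
    input_path: str = ""
    input_format: str = "xyz"           # xyz | csv
    descriptor: str = "soap"            # soap | dmin | phi | none
    soap: dict = field(default_factory=lambda: dict(r_cut=10.0, n_max=4, l_max=4,
                                                    sigma_atom=0.5))
    alignment_r_c: float = 15.0
    denoise_cutoff: float | None = None  # None disables spatial averaging
    pca_k: int = 2
    select_components: list[int] = field(default_factory=list)
    scan_grid_points: int = 20
    onion: dict = field(default_factory=lambda: dict(k_sigma=3.0, min_population=0.01,
                                                     max_states=20))
    bivariate: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _load_input(config: PipelineConfig) -> ParticleTrajectory:
    if config.generate == "two-phase":
        traj, _ = synthetic.gen_two_phase_toy(seed=config.seed, **config.generate_kwargs)
    elif config.generate == "wave":
        traj, _ = synthetic.gen_wave_toy(seed=config.seed, **config.generate_kwargs)
    elif config.generate:
        raise ValueError(f"unknown generator {config.generate!r}")
    elif config.input_format == "xyz":
        traj = read_xyz(config.input_path)
    else:
        traj = read_trajectory_csv(config.input_path)
    return traj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Deterministic for a fixed config (the master seed covers every random
    stage).  Returns the artifact directory.  Any stage error is re-raised
    annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    logging.basicConfig(level=logging.INFO)

    stage = "input"
    try:
        traj = _load_input(config)
        logger.info("input: N=%d T=%d dim=%d", traj.n_particles, traj.n_frames, traj.dim)
        write_xyz(traj, out / "trajectory.xyz") if traj.dim == 3 else \
            write_trajectory_csv(traj, out / "trajectory.csv")

        stage = "descriptor"
        signals: list[SignalEnsemble] = []
        series = None
        if config.descriptor == "soap":
            params = SoapParams(**config.soap)
            series = descriptor_series(traj, params)
            logger.info("descriptor: SOAP D=%d", series.n_components)
        elif config.descriptor == "dmin":
            signals = [d_min(traj)]
        elif config.descriptor == "phi":
            signals = [phi(traj, AlignmentParams(r_c=config.alignment_r_c))]
        elif config.descriptor != "none":
            raise ValueError(f"unknown descriptor {config.descriptor!r}")

        stage = "denoise"
        if config.denoise_cutoff:
            if series is not None:
                series = spatial_average(series, traj, config.denoise_cutoff)
            signals = [spatial_average(s, traj, config.denoise_cutoff) for s in signals]
            logger.info("denoise: cutoff=%s", config.denoise_cutoff)

        stage = "reduce"
        if series is not None:
            if config.select_components:
                signals = [series.extract_component(i) for i in config.select_components]
            else:
                pcs, report = pca_series(series, config.pca_k)
                signals = pcs
                np.savetxt(out / "explained_variance_ratio.csv",
                           report.explained_variance_ratio, delimiter=",",
                           header="explained_variance_ratio (per PC)")
                logger.info("reduce: PCA k=%d cum=%s", config.pca_k,
                            np.round(report.cumulative[:config.pca_k], 4))
        for s in signals:
            write_ensemble_csv(s, out / f"{s.name}.csv", stage="reduce")

        stage = "onion-scan"
        scans = []
        grid = default_grid(signals[0].n_frames, config.scan_grid_points)
        for s in signals:
            scan = delta_t_scan(s, grid=grid, **config.onion)
            scans.append(scan)
            write_scan_csv(scan, out / f"scan_{s.name}.csv", stage="onion-scan")
            logger.info("scan %s: n_states=%s", s.name, scan.n_states)

        stage = "frustration"
        if config.bivariate and len(signals) >= 2:
            scan12 = delta_t_scan(combine(signals[0], signals[1]), grid=grid,
                                  **config.onion)
            write_scan_csv(scan12, out / "scan_bivariate.csv", stage="frustration")
            curve = frustration_gap(scans[0], scans[1], scan12)
            pd.DataFrame({"delta_t_frames": curve.delta_t, "n1": curve.n1,
                          "n2": curve.n2, "n12": curve.n12,
                          "gap_raw": curve.gap_raw,
                          "info_loss": curve.info_loss}).to_csv(
                out / "frustration.csv", index=False)
            logger.info("frustration: max info_loss=%d", int(curve.info_loss.max()))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
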