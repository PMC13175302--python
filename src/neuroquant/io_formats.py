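"""Readers and writers for every external representation.

Formats (all plain text):

- compression CSV: columns ``time,displacement,force`` with sample
  geometry either in ``# key: value`` header comment lines or in a YAML
  sidecar (``<file>.yaml`` next to the CSV).  Units at the boundary are
  s / mm / N with geometry in mm and mm^2; compression is signed
  negative.  Stress conversion to Pa happens once, downstream.
- SWC for traced filaments (id, type, x, y, z, radius, parent; um).
- puncta CSV: ``x,y,z[,intensity]`` in um.
- traces CSV (wide): one ``time`` column plus one column per ROI;
  sampling rate in a ``# rate_hz:`` header comment (default 10 Hz).
- run config YAML and results JSON.

Dialect is strict: comma-separated, dot decimal, UTF-8, mandatory
header row, with a ``delimiter`` escape hatch.  Readers reject
invariant-violating inputs with typed errors naming field and row;
every reader/writer pair round-trips on its own output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calcium import TraceSet
from .errors import (
    GeometryError,
    MissingColumnError,
    MonotonicityError,
    ValidationError,
)
from .morphometry import FilamentModel, PunctaSet

__all__ = [
    "CompressionRecording",
    "RunConfig",
    "read_compression_csv",
    "write_compression_csv",
    "read_filament_swc",
    "write_filament_swc",
    "read_puncta_csv",
    "write_puncta_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_config_yaml",
    "write_results_json",
]


@dataclass
class CompressionRecording:
    """One cyclic unconfined-compression recording plus sample geometry.

    time (s, strictly increasing), displacement (mm, compression
    negative), force (N, compression negative), height_mm and area_mm2
    of the undeformed sample, and free-form metadata (condition, day,
    sample id, temperature, nominal strain rate, ...).
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    height_mm: float
    area_mm2: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if n < 3:
            raise ValidationError(f"recording needs >= 3 samples, got {n}", field="time")
        if self.displacement.size != n or self.force.size != n:
            raise ValidationError("column lengths differ", field="time/displacement/force")
        bad = np.flatnonzero(np.diff(self.time) <= 0)
        if bad.size:
            raise MonotonicityError("time must be strictly increasing",
                                    field="time", row=int(bad[0]) + 1)
        if not (np.isfinite(self.height_mm) and self.height_mm > 0):
            raise GeometryError(f"height must be > 0, got {self.height_mm}", field="height_mm")
        if not (np.isfinite(self.area_mm2) and self.area_mm2 > 0):
            raise GeometryError(f"area must be > 0, got {self.area_mm2}", field="area_mm2")
        for name, arr in (("time", self.time), ("displacement", self.displacement),
                          ("force", self.force)):
            nf = np.flatnonzero(~np.isfinite(arr))
            if nf.size:
                raise ValidationError("non-finite value", field=name, row=int(nf[0]))

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class RunConfig:
    """Analysis configuration with the study protocol as defaults.

    The mechanical protocol: 3 loading cycles to 15% strain; the
    calcium detection contract: SNR 2.2, noise window 1000 frames,
    minimum 2 events per active ROI.
    """

    grid_size: int = 100
    max_strain: float = 0.15
    cycles_expected: int = 3
    alpha_starts: tuple = (-20.0, -5.0, 2.0, 10.0)
    mu_bounds: tuple = (1e-3, 1e7)
    alpha_limit: float = 50.0
    fit_tolerance: float = 1e-12
    snr: float = 2.2
    noise_window: int = 1000
    min_counts: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.max_strain < 1:
            raise ValidationError(f"max_strain must be in (0,1), got {self.max_strain}",
                                  field="max_strain")
        if self.grid_size < 10:
            raise ValidationError("grid_size must be >= 10", field="grid_size")
        if self.fit_tolerance <= 0:
            raise ValidationError("fit_tolerance must be > 0", field="fit_tolerance")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["alpha_starts"] = list(self.alpha_starts)
        d["mu_bounds"] = list(self.mu_bounds)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# --- compression CSV ---------------------------------------------------------

_GEOMETRY_KEYS = ("height_mm", "area_mm2")


def _read_header_comments(path: Path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = yaml.safe_load(val.strip())
    return meta


def read_compression_csv(path, delimiter: str = ",") -> CompressionRecording:
    """Read a compression recording with geometry from header or sidecar.

    Header comment lines ``# height_mm: 3.0`` / ``# area_mm2: 63.617``
    take precedence; otherwise a ``<file>.yaml`` sidecar is consulted.
    Extra header/sidecar keys become metadata.
    """
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta.update(yaml.safe_load(fh) or {})
    meta.update(_read_header_comments(path))
    df = pd.read_csv(path, comment="#", sep=delimiter, float_precision="round_trip")
    for col in ("time", "displacement", "force"):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} missing from {path.name}", field=col)
    height = meta.pop("height_mm", None)
    area = meta.pop("area_mm2", None)
    if height is None:
        raise GeometryError("height_mm missing from header and sidecar", field="height_mm")
    if area is None:
        raise GeometryError("area_mm2 missing from header and sidecar", field="area_mm2")
    return CompressionRecording(
        time=df["time"].to_numpy(),
        displacement=df["displacement"].to_numpy(),
        force=df["force"].to_numpy(),
        height_mm=float(height),
        area_mm2=float(area),
        metadata=meta,
    )


def write_compression_csv(recording: CompressionRecording, path,
                          delimiter: str = ",") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# height_mm: {recording.height_mm!r}\n")
        fh.write(f"# area_mm2: {recording.area_mm2!r}\n")
        for key, val in recording.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(delimiter.join(["time", "displacement", "force"]) + "\n")
        for t, d, f in zip(recording.time, recording.displacement, recording.force):
            # shortest round-trip representation keeps re-reads bit-identical
            fh.write(delimiter.join([repr(float(t)), repr(float(d)),
                                     repr(float(f))]) + "\n")


# --- SWC filaments -----------------------------------------------------------

def read_filament_swc(path) -> FilamentModel:
    """Read an SWC skeleton (id, type, x, y, z, radius, parent; um)."""
    ids, types, coords, radii, parents = [], [], [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValidationError(f"SWC line has {len(parts)} fields, expected 7",
                                      field="swc", row=lineno)
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
    if not ids:
        raise ValidationError("SWC file contains no nodes", field="swc")
    return FilamentModel(node_ids=np.array(ids), xyz=np.array(coords),
                         radius=np.array(radii), parent=np.array(parents),
                         node_type=np.array(types))


def write_filament_swc(filament: FilamentModel, path) -> None:
    types = filament.node_type if filament.node_type is not None \
        else np.zeros(filament.n_nodes, dtype=int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(filament.n_nodes):
            x, y, z = filament.xyz[i]
            fh.write(f"{int(filament.node_ids[i])} {int(types[i])} "
                     f"{x:.6f} {y:.6f} {z:.6f} {filament.radius[i]:.6f} "
                     f"{int(filament.parent[i])}\n")


# --- puncta CSV --------------------------------------------------------------

def read_puncta_csv(path, delimiter: str = ",") -> PunctaSet:
    df = pd.read_csv(path, comment="#", sep=delimiter, float_precision="round_trip")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} missing", field=col)
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    intensity = df["intensity"].to_numpy(dtype=float) if "intensity" in df.columns else None
    return PunctaSet(xyz=xyz, intensity=intensity)


def write_puncta_csv(puncta: PunctaSet, path, delimiter: str = ",") -> None:
    cols = {"x": puncta.xyz[:, 0], "y": puncta.xyz[:, 1], "z": puncta.xyz[:, 2]}
    if puncta.intensity is not None:
        cols["intensity"] = puncta.intensity
    pd.DataFrame(cols).to_csv(path, index=False, sep=delimiter,
                              float_format="%.17g")


# --- traces CSV --------------------------------------------------------------

def read_trace_csv(path, delimiter: str = ",", rate_hz: float | None = None) -> TraceSet:
    """Read a wide ROI-trace table: ``time`` column plus one column per ROI.

    The sampling rate comes from a ``# rate_hz:`` header comment, the
    ``rate_hz`` argument, or defaults to 10 Hz.
    """
    path = Path(path)
    meta = _read_header_comments(path)
    rate = float(rate_hz if rate_hz is not None else meta.get("rate_hz", 10.0))
    df = pd.read_csv(path, comment="#", sep=delimiter, float_precision="round_trip")
    roi_cols = [c for c in df.columns if c != "time"]
    if not roi_cols:
        raise MissingColumnError("no ROI columns found", field="roi")
    for col in roi_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise ValidationError("non-finite trace value", field=col, row=int(bad[0]))
    data = df[roi_cols].to_numpy(dtype=float).T
    return TraceSet(data=data, rate_hz=rate, roi_ids=roi_cols)


def write_trace_csv(traces: TraceSet, path, delimiter: str = ",") -> None:
    t = np.arange(traces.n_frames) / traces.rate_hz
    df = pd.DataFrame({"time": t})
    for i, roi in enumerate(traces.roi_ids):
        df[roi] = traces.data[i]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate_hz: {traces.rate_hz!r}\n")
        df.to_csv(fh, index=False, sep=delimiter, float_format="%.17g")


# --- results & config --------------------------------------------------------

def write_results_json(results: dict, path) -> None:
    """Write an analysis-results dict as JSON (numpy types coerced)."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if hasattr(obj, "__dict__"):
            return vars(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, default=_default)


def read_config_yaml(path) -> RunConfig:
    return RunConfig.from_yaml(path)
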