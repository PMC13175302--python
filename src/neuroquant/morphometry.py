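"""Geometric quantification of imaging-derived 3D objects.

Works on the *outputs* of commercial tracing/detection tools: a traced
neurite skeleton with per-node radii (SWC-style), 3D synaptic-marker
puncta coordinates, and live/dead object counts.  Provides

- distance from a point to the filament *surface* (capsule union:
  segments with linearly interpolated radii and spherical end caps),
- the puncta-near-filament inclusion rule (surface distance <= 2.5 um,
  the z-step interval of the image stacks, inclusive),
- synapse density normalized per 100 um^3 of neuronal volume and per
  100 um of neurite length,
- per-image mean neurite length, and live/dead viability percentages.

All coordinates and radii are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FilamentTopologyError, ValidationError

__all__ = [
    "FilamentModel",
    "PunctaSet",
    "DensityResult",
    "ViabilityResult",
    "distance_to_filament_surface",
    "count_puncta_near_filament",
    "synapse_density",
    "neurite_mean_length",
    "viability_percent",
    "DEFAULT_SURFACE_THRESHOLD_UM",
]

#: Inclusion threshold for puncta near the filament surface (um).
#: Corresponds to the axial (z) step interval of the image stacks.
DEFAULT_SURFACE_THRESHOLD_UM = 2.5


@dataclass
class FilamentModel:
    """Traced skeleton: nodes with radii plus parent links forming a forest.

    Attributes
    ----------
    node_ids : ndarray of int
        Unique node identifiers (SWC sample numbers).
    xyz : ndarray, shape (n, 3)
        Node coordinates, um.
    radius : ndarray
        Per-node radius, um, >= 0.
    parent : ndarray of int
        Parent node id per node; -1 marks a root.
    """

    node_ids: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    node_type: np.ndarray | None = None
    _segments: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.node_ids.size
        if self.xyz.shape != (n, 3) or self.radius.size != n or self.parent.size != n:
            raise ValidationError("node arrays have inconsistent lengths", field="nodes")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("non-finite node coordinate", field="xyz")
        bad = np.flatnonzero(self.radius < 0)
        if bad.size:
            raise ValidationError("negative radius", field="radius", row=int(bad[0]))
        if np.unique(self.node_ids).size != n:
            raise ValidationError("duplicate node ids", field="id")
        id_to_idx = {int(i): k for k, i in enumerate(self.node_ids)}
        for k, p in enumerate(self.parent):
            if p != -1 and int(p) not in id_to_idx:
                raise FilamentTopologyError(
                    f"node {int(self.node_ids[k])} references missing parent {int(p)}",
                    field="parent", row=k,
                )
        self._check_acyclic(id_to_idx)
        self._id_to_idx = id_to_idx

    def _check_acyclic(self, id_to_idx):
        state = {}  # 0 visiting, 1 done
        for start in self.node_ids:
            path = []
            i = int(start)
            while i != -1 and state.get(i) != 1:
                if state.get(i) == 0:
                    raise FilamentTopologyError(f"cycle through node {i}", field="parent")
                state[i] = 0
                path.append(i)
                i = int(self.parent[id_to_idx[i]])
            for j in path:
                state[j] = 1

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    def segments(self):
        """(p0, p1, r0, r1) arrays for every child->parent edge."""
        if self._segments is None:
            child = np.flatnonzero(self.parent != -1)
            pidx = np.array([self._id_to_idx[int(p)] for p in self.parent[child]], dtype=int)
            self._segments = (self.xyz[pidx], self.xyz[child],
                              self.radius[pidx], self.radius[child])
        return self._segments

    @property
    def n_segments(self) -> int:
        return self.segments()[0].shape[0]

    @property
    def total_length_um(self) -> float:
        p0, p1, _, _ = self.segments()
        if p0.shape[0] == 0:
            return 0.0
        return float(np.linalg.norm(p1 - p0, axis=1).sum())

    @property
    def volume_um3(self) -> float:
        """Sum of conical-frustum volumes; no overlap correction at branches."""
        p0, p1, r0, r1 = self.segments()
        if p0.shape[0] == 0:
            return 0.0
        length = np.linalg.norm(p1 - p0, axis=1)
        return float((np.pi / 3.0 * length * (r0**2 + r0 * r1 + r1**2)).sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FilamentModel":
        """Rigidly transformed copy (3x3 rotation then translation)."""
        return FilamentModel(
            node_ids=self.node_ids.copy(),
            xyz=self.xyz @ np.asarray(rotation).T + np.asarray(translation),
            radius=self.radius.copy(),
            parent=self.parent.copy(),
            node_type=None if self.node_type is None else self.node_type.copy(),
        )


@dataclass
class PunctaSet:
    """3D point set of detected puncta (um), with optional intensities."""

    xyz: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("non-finite puncta coordinate", field="xyz")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.size != self.xyz.shape[0]:
                raise ValidationError("intensity length mismatch", field="intensity")

    def __len__(self) -> int:
        return int(self.xyz.shape[0])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PunctaSet":
        return PunctaSet(self.xyz @ np.asarray(rotation).T + np.asarray(translation),
                         None if self.intensity is None else self.intensity.copy())


@dataclass(frozen=True)
class DensityResult:
    """Synapse density summaries for one filament model."""

    included: int
    total_puncta: int
    volume_um3: float
    length_um: float
    density_per_100um3: float
    density_per_100um: float


@dataclass(frozen=True)
class ViabilityResult:
    live: int
    dead: int
    percent_viable: float


def distance_to_filament_surface(points, filament: FilamentModel):
    """Minimum distance (um) from point(s) to the filament surface.

    The surface is the union of capsules: for each skeleton segment the
    point-to-axis distance minus the linearly interpolated local radius,
    clamped at zero (points inside the surface are at distance 0).
    Vectorized over points and segments.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    p0, p1, r0, r1 = filament.segments()
    if p0.shape[0] == 0:
        raise ValidationError("filament has no segments", field="segments")
    axis = p1 - p0                                   # (m, 3)
    seg_len2 = np.einsum("ij,ij->i", axis, axis)     # (m,)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    diff = pts[:, None, :] - p0[None, :, :]          # (n, m, 3)
    t = np.einsum("nmj,mj->nm", diff, axis) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    closest = p0[None, :, :] + t[..., None] * axis[None, :, :]
    axial_dist = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    local_radius = r0[None, :] + t * (r1 - r0)[None, :]
    surf = np.clip(axial_dist - local_radius, 0.0, None)
    out = surf.min(axis=1)
    return out if np.asarray(points).ndim > 1 else float(out[0])


def count_puncta_near_filament(puncta: PunctaSet, filament: FilamentModel,
                               threshold_um: float = DEFAULT_SURFACE_THRESHOLD_UM) -> int:
    """Number of puncta within ``threshold_um`` of the filament surface.

    The boundary is inclusive: a punctum at exactly the threshold counts.
    """
    if threshold_um <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold_um}", field="threshold")
    if len(puncta) == 0:
        return 0
    d = distance_to_filament_surface(puncta.xyz, filament)
    return int(np.count_nonzero(d <= threshold_um))


def synapse_density(included: int, filament: FilamentModel,
                    total_puncta: int | None = None) -> DensityResult:
    """Density of included puncta per 100 um^3 volume and per 100 um length."""
    volume = filament.volume_um3
    length = filament.total_length_um
    if volume <= 0:
        raise ValidationError("filament volume is zero", field="volume")
    if length <= 0:
        raise ValidationError("filament length is zero", field="length")
    return DensityResult(
        included=int(included),
        total_puncta=int(total_puncta if total_puncta is not None else included),
        volume_um3=volume,
        length_um=length,
        density_per_100um3=100.0 * included / volume,
        density_per_100um=100.0 * included / length,
    )


def neurite_mean_length(filaments) -> float:
    """Arithmetic mean of per-filament total lengths (um) for one image."""
    filaments = list(filaments)
    if not filaments:
        raise ValidationError("empty filament list", field="filaments")
    return float(np.mean([f.total_length_um for f in filaments]))


def viability_percent(live: int, dead: int) -> ViabilityResult:
    """Percentage of live objects among live + dead."""
    if live < 0 or dead < 0:
        raise ValidationError("counts must be non-negative", field="live/dead")
    if live + dead == 0:
        raise ValidationError("live + dead must be > 0", field="live/dead")
    return ViabilityResult(live=int(live), dead=int(dead),
                           percent_viable=100.0 * live / (live + dead))
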