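"""Preprocessing of cyclic unconfined-compression recordings.

Turns a raw (time, displacement, force) recording into the averaged
hyperelastic stress-stretch curves that constitutive fitting consumes:

1. kinematics — stretch ``lam = 1 + dz/h`` and nominal stress
   ``Pzz = f_z / A`` (force over the *undeformed* cross-section);
2. segmentation of the displacement waveform into per-cycle loading and
   unloading phases;
3. phase averaging — loading and unloading of a cycle are interpolated
   onto a shared uniform stretch grid and averaged pointwise, which
   removes symmetric hysteresis and approximates the hyperelastic
   response.  Cycle 1 gives the *unconditioned*, cycle 3 the
   *conditioned* response.

Compression is signed negative internally (displacement, force and
stress); reporting layers print magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import medfilt

from .errors import (
    CycleCountError,
    GeometryError,
    NonPhysicalDeformationError,
    PhaseTagError,
    ValidationError,
)

__all__ = [
    "StretchState",
    "HyperelasticCurve",
    "compute_stretch",
    "compute_nominal_stress",
    "segment_cycles",
    "average_load_unload",
    "max_nominal_stress",
    "preprocess_recording",
]


@dataclass(frozen=True)
class StretchState:
    """Principal stretches of incompressible uniaxial compression.

    ``lam`` is the axial stretch; the lateral stretches are
    ``lam**-0.5`` each, so the volume ratio ``J`` is identically 1.
    """

    lam: float

    def __post_init__(self):
        if self.lam <= 0:
            raise NonPhysicalDeformationError(
                f"axial stretch must be > 0, got {self.lam}", field="lam"
            )

    @property
    def lateral(self) -> float:
        return self.lam ** -0.5

    @property
    def principal_stretches(self) -> tuple[float, float, float]:
        return (self.lateral, self.lateral, self.lam)

    @property
    def volume_ratio(self) -> float:
        l1, l2, l3 = self.principal_stretches
        return l1 * l2 * l3


@dataclass
class HyperelasticCurve:
    """Paired (stretch, nominal stress) samples with cycle/phase tags.

    Attributes
    ----------
    lam : ndarray
        Dimensionless axial stretch, each in (0, 1.5).
    pzz : ndarray
        Nominal stress, Pa (negative in compression).
    cycle : int
        1-based compression-cycle index.
    phase : {"loading", "unloading", "averaged"}
    label : {"unconditioned", "conditioned", "none"}
        Unconditioned = averaged cycle 1, conditioned = averaged cycle 3.
    """

    lam: np.ndarray
    pzz: np.ndarray
    cycle: int
    phase: str
    label: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.pzz = np.asarray(self.pzz, dtype=float)
        if self.lam.shape != self.pzz.shape:
            raise ValidationError(
                f"lam and pzz lengths differ: {self.lam.size} vs {self.pzz.size}",
                field="lam/pzz",
            )
        if self.phase not in ("loading", "unloading", "averaged"):
            raise ValidationError(f"unknown phase {self.phase!r}", field="phase")
        if self.label not in ("unconditioned", "conditioned", "none"):
            raise ValidationError(f"unknown label {self.label!r}", field="label")
        if self.lam.size and (np.any(self.lam <= 0) or np.any(self.lam >= 1.5)):
            raise ValidationError("stretch values must lie in (0, 1.5)", field="lam")

    def __len__(self) -> int:
        return int(self.lam.size)

    def sorted_by_stretch(self) -> "HyperelasticCurve":
        order = np.argsort(self.lam)
        return replace(self, lam=self.lam[order], pzz=self.pzz[order])

    def to_dict(self) -> dict:
        return {
            "lam": self.lam.tolist(),
            "pzz_pa": self.pzz.tolist(),
            "cycle": self.cycle,
            "phase": self.phase,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperelasticCurve":
        return cls(
            lam=np.asarray(d["lam"], dtype=float),
            pzz=np.asarray(d["pzz_pa"], dtype=float),
            cycle=int(d["cycle"]),
            phase=str(d["phase"]),
            label=str(d.get("label", "none")),
        )


def compute_stretch(dz_mm, height_mm: float):
    """Axial stretch ``lam = 1 + dz/h`` from signed z-displacement.

    Compressive displacement is negative, so ``lam < 1`` in compression;
    15% strain corresponds to ``lam = 0.85``.
    """
    if height_mm <= 0:
        raise GeometryError(f"sample height must be > 0, got {height_mm}", field="height")
    lam = 1.0 + np.asarray(dz_mm, dtype=float) / float(height_mm)
    if np.any(lam <= 0):
        raise NonPhysicalDeformationError(
            "displacement implies stretch <= 0 (sample fully collapsed)", field="displacement"
        )
    return lam


def compute_nominal_stress(fz_n, area_mm2: float):
    """Nominal (Piola) stress Pzz in Pa: axial force over undeformed area.

    Force in newtons (compression negative), area in mm^2; the mm^2 -> m^2
    conversion happens here, once.
    """
    if area_mm2 <= 0:
        raise GeometryError(f"cross-sectional area must be > 0, got {area_mm2}", field="area")
    return np.asarray(fz_n, dtype=float) / (float(area_mm2) * 1e-6)


def _turning_points(displacement: np.ndarray, smooth_window: int = 5):
    """Trough and boundary indices of a cyclic triangular-ish waveform.

    The displacement is smoothed with a moving median (robust to sensor
    jitter); troughs are the per-cycle compression minima, boundaries the
    near-zero returns separating cycles.
    """
    d = np.asarray(displacement, dtype=float)
    if smooth_window > 1 and d.size >= smooth_window:
        w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
        d = medfilt(d, kernel_size=w)
    dmin = d.min()
    if dmin >= 0:
        return [], []
    # sign of the first difference: -1 while compressing, +1 while releasing
    diff = np.diff(d)
    sign = np.sign(diff)
    # carry forward the last nonzero sign through flat runs
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    raw = np.asarray(displacement, dtype=float)
    troughs = []
    for i in range(1, sign.size):
        # local minimum; keep only substantial troughs (> half max depth)
        if sign[i - 1] < 0 and sign[i] > 0 and d[i] < 0.5 * dmin:
            troughs.append(i)
    # the median filter flattens extrema; refine each trough to the raw
    # minimum within the smoothing neighborhood
    half = max(smooth_window, 2)
    troughs = [max(0, i - half) + int(np.argmin(raw[max(0, i - half):i + half + 1]))
               for i in troughs]
    troughs = sorted(set(troughs))
    # one boundary per cycle: the highest raw point between consecutive troughs
    boundaries = [0]
    for a, b in zip(troughs[:-1], troughs[1:]):
        boundaries.append(a + int(np.argmax(raw[a:b + 1])))
    boundaries.append(d.size - 1)
    return troughs, boundaries


def segment_cycles(recording, expected_cycles: int = 3,
                   smooth_window: int = 5) -> list[HyperelasticCurve]:
    """Split a cyclic recording into tagged loading/unloading phase curves.

    Returns ``2 * expected_cycles`` curves in time order: loading then
    unloading per cycle, each already converted to (stretch, Pzz).

    Raises
    ------
    CycleCountError
        If the number of detected compression troughs differs from
        ``expected_cycles``; the error carries the detected turning
        indices for diagnosis.
    """
    troughs, boundaries = _turning_points(recording.displacement, smooth_window)
    if len(troughs) != expected_cycles:
        raise CycleCountError(
            f"detected {len(troughs)} complete cycles, expected {expected_cycles} "
            f"(turning indices: {troughs})",
            detected=len(troughs),
            expected=expected_cycles,
            turning_indices=list(troughs),
        )
    lam = compute_stretch(recording.displacement, recording.height_mm)
    pzz = compute_nominal_stress(recording.force, recording.area_mm2)

    curves: list[HyperelasticCurve] = []
    for k, trough in enumerate(troughs, start=1):
        start = boundaries[k - 1]
        end = boundaries[k]
        load = slice(start, trough + 1)
        unload = slice(trough, end + 1)
        curves.append(HyperelasticCurve(lam[load], pzz[load], cycle=k, phase="loading",
                                        meta={"start": start, "trough": trough}))
        curves.append(HyperelasticCurve(lam[unload], pzz[unload], cycle=k, phase="unloading",
                                        meta={"trough": trough, "end": end}))
    return curves


def average_load_unload(loading: HyperelasticCurve, unloading: HyperelasticCurve,
                        grid_size: int = 100) -> HyperelasticCurve:
    """Average a loading/unloading pair onto a uniform stretch grid.

    Both phases are linearly interpolated onto ``grid_size`` uniformly
    spaced stretch values over their common range and averaged pointwise.
    Symmetric (multiplicative) hysteresis cancels exactly under this
    operation.  The result is labelled *unconditioned* for cycle 1 and
    *conditioned* for cycle 3.
    """
    if loading.phase != "loading" or unloading.phase != "unloading":
        raise PhaseTagError(
            f"expected (loading, unloading) pair, got ({loading.phase}, {unloading.phase})",
            field="phase",
        )
    if loading.cycle != unloading.cycle:
        raise PhaseTagError(
            f"cycle tags differ: {loading.cycle} vs {unloading.cycle}", field="cycle"
        )
    lo = loading.sorted_by_stretch()
    un = unloading.sorted_by_stretch()
    low = max(lo.lam.min(), un.lam.min())
    high = min(lo.lam.max(), un.lam.max())
    if not high > low:
        raise ValidationError(
            f"loading and unloading stretch ranges do not overlap "
            f"([{lo.lam.min():.4g}, {lo.lam.max():.4g}] vs "
            f"[{un.lam.min():.4g}, {un.lam.max():.4g}])",
            field="lam",
        )
    grid = np.linspace(low, high, grid_size)
    p_load = np.interp(grid, lo.lam, lo.pzz)
    p_unload = np.interp(grid, un.lam, un.pzz)
    label = {1: "unconditioned", 3: "conditioned"}.get(loading.cycle, "none")
    return HyperelasticCurve(grid, 0.5 * (p_load + p_unload),
                             cycle=loading.cycle, phase="averaged", label=label)


def max_nominal_stress(first_loading: HyperelasticCurve) -> float:
    """Maximum |Pzz| (Pa) over the first loading phase.

    This is the per-sample scalar the study compares across conditions
    (reported in kPa at the presentation layer).
    """
    if first_loading.phase != "loading" or first_loading.cycle != 1:
        raise PhaseTagError(
            f"max nominal stress is defined on the cycle-1 loading curve, got "
            f"cycle {first_loading.cycle} {first_loading.phase}",
            field="phase",
        )
    if len(first_loading) == 0:
        raise ValidationError("empty curve", field="pzz")
    return float(np.max(np.abs(first_loading.pzz)))


def preprocess_recording(recording, expected_cycles: int = 3, grid_size: int = 100) -> dict:
    """Full preprocessing pipeline for one recording.

    Returns a dict with the averaged ``unconditioned`` (cycle 1) and
    ``conditioned`` (cycle 3, if present) curves, the raw phase curves,
    and the first-cycle ``max_stress_pa``.
    """
    phases = segment_cycles(recording, expected_cycles=expected_cycles)
    by_cycle = {}
    for c in phases:
        by_cycle.setdefault(c.cycle, {})[c.phase] = c
    out = {
        "phases": phases,
        "max_stress_pa": max_nominal_stress(by_cycle[1]["loading"]),
        "unconditioned": average_load_unload(by_cycle[1]["loading"],
                                             by_cycle[1]["unloading"], grid_size),
    }
    last = max(by_cycle)
    if last >= 3:
        out["conditioned"] = average_load_unload(by_cycle[3]["loading"],
                                                 by_cycle[3]["unloading"], grid_size)
    return out
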