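"""Seeded synthetic-data generators with ground truth for every stage.

Each generator emulates the statistical structure its consumer assumes
and returns its ground truth alongside the data, so every pipeline
stage is testable without instrument recordings:

- cyclic compression recordings built around the analytic Ogden
  uniaxial stress, with the study protocol as defaults (3 cycles to 15%
  strain at 0.01/s), symmetric multiplicative hysteresis (loading
  (1+eta), unloading (1-eta) — so phase averaging recovers the baseline
  exactly), a single multiplicative cycle-3 softening factor s
  (Mullins-like conditioning as data, not as a constitutive law), and
  multiplicative Gaussian noise;
- random filament scenes with puncta rejection-sampled inside the
  2.5 um surface shell and strictly outside a wider margin, at known
  counts;
- calcium traces with Poisson-timed exponential transients on a
  constant baseline (10 Hz, 300 s defaults) and per-event analytic
  AUC = A * tau;
- labeled group draws for the statistics router.

All randomness flows from one explicit seed per spec; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ValidationError
from .io_formats import CompressionRecording
from .morphometry import FilamentModel, PunctaSet, distance_to_filament_surface
from .calcium import TraceSet
from .group_stats import GroupData
from .ogden import OgdenParameters, uniaxial_nominal_stress

__all__ = [
    "MechSimSpec", "MechTruth", "generate_cyclic_recording",
    "SceneSpec", "SceneTruth", "generate_scene",
    "CalciumSimSpec", "CalciumTruth", "generate_calcium_traces",
    "GroupSpec", "generate_group_data",
]


# --- mechanics ---------------------------------------------------------------

@dataclass(frozen=True)
class MechSimSpec:
    """Simulation spec for a cyclic unconfined-compression recording.

    Protocol defaults mirror the study: three cycles to 15% maximum
    strain at a strain rate of 0.01/s.  ``eta`` is the symmetric
    hysteresis factor (loading stress scaled by 1+eta, unloading by
    1-eta), ``conditioning`` the multiplicative cycle-3 softening, and
    ``noise`` the multiplicative Gaussian stress-noise sigma.
    """

    mu: float = 150.0
    alpha: float = -10.0
    max_strain: float = 0.15
    strain_rate: float = 0.01        # 1/s
    cycles: int = 3
    eta: float = 0.1
    conditioning: float = 0.85       # cycle-3 multiplicative softening s
    noise: float = 0.0
    seed: int = 0
    height_mm: float = 3.0
    area_mm2: float = 63.617         # 9 mm diameter punch: pi * 4.5^2
    sample_rate_hz: float = 10.0

    def __post_init__(self):
        if not 0 <= self.eta < 0.5:
            raise ValidationError(f"eta must be in [0, 0.5), got {self.eta}", field="eta")
        if not 0 < self.conditioning <= 1:
            raise ValidationError("conditioning must be in (0, 1]", field="conditioning")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0", field="noise")
        if not 0 < self.max_strain < 1:
            raise ValidationError("max_strain must be in (0,1)", field="max_strain")

    @property
    def aligned_grid_size(self) -> int:
        """Averaging-grid size whose nodes coincide with sample stretches.

        One node per sample of a half-cycle; on this grid the phase
        average of the symmetric hysteresis pair reproduces the Ogden
        baseline exactly (no interpolation error between samples).
        """
        return int(round(self.max_strain / self.strain_rate * self.sample_rate_hz)) + 1


@dataclass(frozen=True)
class MechTruth:
    """Ground truth accompanying a simulated recording."""

    mu: float
    alpha: float
    eta: float
    conditioning: float
    trough_indices: tuple
    boundary_indices: tuple

    def baseline_stress(self, lam):
        """Noise-free hysteresis-free Ogden stress at the true parameters."""
        return uniaxial_nominal_stress(lam, OgdenParameters(self.mu, self.alpha))


def generate_cyclic_recording(spec: MechSimSpec):
    """Simulate one recording; returns (CompressionRecording, MechTruth).

    The displacement is a triangular waveform between 0 and
    ``-max_strain * height``; each half-phase lasts
    ``max_strain / strain_rate`` seconds.  The force is
    ``area * Pzz(lam)`` with the phase/cycle scalings and multiplicative
    noise applied.
    """
    rng = np.random.default_rng(spec.seed)
    phase_t = spec.max_strain / spec.strain_rate           # s per half-cycle
    dt = 1.0 / spec.sample_rate_hz
    n_phases = 2 * spec.cycles
    total_t = n_phases * phase_t
    t = np.arange(0.0, total_t + 0.5 * dt, dt)
    knot_t = np.arange(n_phases + 1) * phase_t
    knot_dz = np.tile([0.0, -spec.max_strain * spec.height_mm], spec.cycles + 1)[:n_phases + 1]
    dz = np.interp(t, knot_t, knot_dz)

    lam = 1.0 + dz / spec.height_mm
    params = OgdenParameters(spec.mu, spec.alpha)
    pzz = uniaxial_nominal_stress(lam, params)

    # phase index per sample: 0-based half-cycle; even = loading, odd = unloading
    phase_idx = np.minimum((t / phase_t).astype(int), n_phases - 1)
    loading_mask = phase_idx % 2 == 0
    scale = np.where(loading_mask, 1.0 + spec.eta, 1.0 - spec.eta)
    # the two branches of a hysteresis loop meet at the turning points, so
    # samples landing exactly on a waveform knot carry the baseline value
    on_knot = np.isclose(t % phase_t, 0.0, atol=0.25 * dt) \
        | np.isclose(t % phase_t, phase_t, atol=0.25 * dt)
    scale[on_knot] = 1.0
    cycle_idx = phase_idx // 2 + 1
    if spec.cycles >= 3:
        scale = scale * np.where(cycle_idx == 3, spec.conditioning, 1.0)
    pzz = pzz * scale
    if spec.noise > 0:
        pzz = pzz * (1.0 + spec.noise * rng.standard_normal(pzz.shape))

    force = pzz * spec.area_mm2 * 1e-6                     # Pa * m^2 -> N
    troughs = tuple(int(round((2 * k + 1) * phase_t / dt)) for k in range(spec.cycles))
    boundaries = (0,) + tuple(int(round(2 * k * phase_t / dt)) for k in range(1, spec.cycles)) \
        + (t.size - 1,)
    rec = CompressionRecording(
        time=t, displacement=dz, force=force,
        height_mm=spec.height_mm, area_mm2=spec.area_mm2,
        metadata={"condition": "synthetic", "strain_rate": spec.strain_rate,
                  "max_strain": spec.max_strain, "seed": spec.seed},
    )
    truth = MechTruth(mu=spec.mu, alpha=spec.alpha, eta=spec.eta,
                      conditioning=spec.conditioning,
                      trough_indices=troughs, boundary_indices=boundaries)
    return rec, truth


# --- morphometry scenes ------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Spec for a random filament + puncta scene with known shell counts."""

    n_nodes: int = 20
    box_um: float = 60.0
    radius_um: float = 0.5
    n_inside: int = 30               # puncta within the <= threshold shell
    n_outside: int = 70              # puncta strictly beyond the outside margin
    threshold_um: float = 2.5
    outside_margin_um: float = 2.6
    step_um: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValidationError("need >= 2 nodes", field="n_nodes")
        if self.n_inside < 0 or self.n_outside < 0:
            raise ValidationError("counts must be >= 0", field="n_inside/n_outside")
        if self.outside_margin_um <= self.threshold_um:
            raise ValidationError("outside margin must exceed threshold",
                                  field="outside_margin_um")


@dataclass(frozen=True)
class SceneTruth:
    n_inside: int
    n_outside: int
    threshold_um: float


def _random_filament(rng, spec: SceneSpec) -> FilamentModel:
    """Random-walk polyline folded back into the box interior."""
    lo, hi = 0.15 * spec.box_um, 0.85 * spec.box_um
    pts = np.empty((spec.n_nodes, 3))
    pts[0] = rng.uniform(lo, hi, size=3)
    for i in range(1, spec.n_nodes):
        step = rng.normal(size=3)
        step *= spec.step_um / np.linalg.norm(step)
        pts[i] = np.clip(pts[i - 1] + step, lo, hi)
    ids = np.arange(1, spec.n_nodes + 1)
    parent = np.concatenate([[-1], ids[:-1]])
    return FilamentModel(node_ids=ids, xyz=pts,
                         radius=np.full(spec.n_nodes, spec.radius_um),
                         parent=parent)


def generate_scene(spec: SceneSpec):
    """Random scene; returns (FilamentModel, PunctaSet, SceneTruth).

    Inside puncta are placed by sampling a point on a random segment
    axis and offsetting it radially to a surface distance drawn
    uniformly from (0, threshold]; adding further segments can only
    shrink the surface distance, so the point stays inside the shell.
    Outside puncta are uniform box draws accepted only beyond the
    outside margin; an overfull box raises ``GenerationError``.
    """
    rng = np.random.default_rng(spec.seed)
    filament = _random_filament(rng, spec)
    p0, p1, r0, r1 = filament.segments()
    n_seg = p0.shape[0]

    points = []
    for _ in range(spec.n_inside):
        for _attempt in range(200):
            s = rng.integers(n_seg)
            tloc = rng.uniform()
            axis_pt = p0[s] + tloc * (p1[s] - p0[s])
            radius = r0[s] + tloc * (r1[s] - r0[s])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(0.0, spec.threshold_um)
            cand = axis_pt + direction * (radius + dist)
            if distance_to_filament_surface(cand[None, :], filament)[0] <= spec.threshold_um:
                points.append(cand)
                break
        else:  # pragma: no cover - essentially unreachable
            raise GenerationError("could not place an inside punctum")
    for _ in range(spec.n_outside):
        for _attempt in range(2000):
            cand = rng.uniform(0.0, spec.box_um, size=3)
            if distance_to_filament_surface(cand[None, :], filament)[0] > spec.outside_margin_um:
                points.append(cand)
                break
        else:
            raise GenerationError(
                "box too small to place puncta outside the margin; enlarge box_um")
    xyz = np.asarray(points).reshape(-1, 3)
    return filament, PunctaSet(xyz=xyz), SceneTruth(
        n_inside=spec.n_inside, n_outside=spec.n_outside, threshold_um=spec.threshold_um)


# --- calcium traces ----------------------------------------------------------

@dataclass(frozen=True)
class CalciumSimSpec:
    """Spec for Poisson-event calcium traces (dF/F units internally).

    ``amplitude_sigma`` is the event-amplitude range expressed in units
    of the noise sigma; with ``noise_sigma = 0`` the amplitudes are
    absolute dF/F values instead.  ``f0`` is the constant per-ROI raw
    baseline; raw traces are ``f0 * (1 + dff)``.
    """

    n_roi: int = 50
    duration_s: float = 300.0
    rate_hz: float = 10.0
    event_rate_hz: float = 0.02
    amplitude_sigma: tuple = (6.0, 10.0)
    tau_s: float = 2.0
    noise_sigma: float = 0.02        # dF/F units
    f0: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValidationError("rate and duration must be > 0", field="rate/duration")
        if self.event_rate_hz < 0 or self.noise_sigma < 0:
            raise ValidationError("rates and sigmas must be >= 0", field="event_rate/noise")


@dataclass(frozen=True)
class CalciumTruth:
    """Per-ROI event times, dF/F amplitudes and analytic AUCs (A * tau)."""

    event_times: tuple      # tuple of per-ROI arrays (s)
    amplitudes: tuple       # tuple of per-ROI arrays (dF/F)
    aucs: tuple             # tuple of per-ROI arrays (dF/F * s)
    event_rate_hz: float


def generate_calcium_traces(spec: CalciumSimSpec):
    """Simulate traces; returns (TraceSet, CalciumTruth).

    Per ROI: homogeneous-Poisson event times over the recording, snapped
    to the sampling grid (so the peak is actually sampled and the
    analytic per-event AUC ``A * tau`` is attainable by integration of
    the trace); each event adds ``A * exp(-(t - t0)/tau)`` for t >= t0;
    Gaussian noise of ``noise_sigma`` rides on top; the raw trace is
    ``f0 * (1 + dff)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n_frames) / spec.rate_hz
    amp_scale = spec.noise_sigma if spec.noise_sigma > 0 else 1.0
    data = np.empty((spec.n_roi, n_frames))
    all_times, all_amps, all_aucs = [], [], []
    for i in range(spec.n_roi):
        n_events = rng.poisson(spec.event_rate_hz * spec.duration_s)
        times = np.sort(rng.uniform(0.0, spec.duration_s, size=n_events))
        times = np.round(times * spec.rate_hz) / spec.rate_hz
        amps = rng.uniform(*spec.amplitude_sigma, size=n_events) * amp_scale
        dff = np.zeros(n_frames)
        for t0, a in zip(times, amps):
            mask = t >= t0
            dff[mask] += a * np.exp(-(t[mask] - t0) / spec.tau_s)
        if spec.noise_sigma > 0:
            dff += spec.noise_sigma * rng.standard_normal(n_frames)
        data[i] = spec.f0 * (1.0 + dff)
        all_times.append(times)
        all_amps.append(amps)
        all_aucs.append(amps * spec.tau_s)
    traces = TraceSet(data=data, rate_hz=spec.rate_hz,
                      roi_ids=[f"roi{i:03d}" for i in range(spec.n_roi)])
    truth = CalciumTruth(event_times=tuple(all_times), amplitudes=tuple(all_amps),
                         aucs=tuple(all_aucs), event_rate_hz=spec.event_rate_hz)
    return traces, truth


# --- group data --------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One group's sampling distribution for the statistics router."""

    label: str
    dist: str = "normal"             # normal | exponential | lognormal
    loc: float = 0.0
    scale: float = 1.0
    n: int = 10


def generate_group_data(specs, seed: int = 0, design: str = "one-way"):
    """Draw labeled groups; returns (GroupData, truth dict).

    Truth records each group's distribution family and parameters plus
    whether the configuration is a true null (all families and moments
    identical).
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValidationError("need >= 2 group specs", field="specs")
    rng = np.random.default_rng(seed)
    groups = {}
    for s in specs:
        if s.dist == "normal":
            vals = rng.normal(s.loc, s.scale, size=s.n)
        elif s.dist == "exponential":
            vals = s.loc + rng.exponential(s.scale, size=s.n)
        elif s.dist == "lognormal":
            vals = s.loc + rng.lognormal(sigma=s.scale, size=s.n)
        else:
            raise ValidationError(f"unknown distribution {s.dist!r}", field="dist")
        groups[s.label] = vals
    data = GroupData(groups=groups, design=design)
    null = len({(s.dist, s.loc, s.scale) for s in specs}) == 1
    truth = {"null": null,
             "families": {s.label: s.dist for s in specs},
             "params": {s.label: (s.loc, s.scale) for s in specs}}
    return data, truth
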