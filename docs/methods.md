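# Methods

This note documents the models, numerical choices and limitations behind
`neuroquant`, in the order the pipeline runs.

## Mechanical model

Unconfined uniaxial compression of a soft, quasi-incompressible sample is
described by the axial stretch λ = 1 + Δz/h (Δz the signed z-displacement,
h the undeformed height; compression has Δz < 0 and λ < 1, so the
protocol's 15% strain is λ = 0.85).  Assuming isotropy and isochoric
deformation (det **F** = 1), the lateral stretches are λ^(−1/2) and the
Poisson ratio is 0.5.  The measured stress is the nominal (first Piola)
stress P_zz = f_z / A with A the *undeformed* cross-section; forces and
stresses are signed negative in compression internally, and magnitudes are
printed at the reporting layer.

The constitutive law is the incompressible one-term modified Ogden model

    ψ(λ1, λ2, λ3) = (2μ/α²)(λ1^α + λ2^α + λ3^α − 3),

with shear modulus μ (Pa) and dimensionless nonlinearity α.  Enforcing the
lateral traction-free boundary condition fixes the hydrostatic pressure
p = (2μ/α) λ^(−α/2) and yields the closed-form axial nominal stress

    P_zz(λ) = (2μ/α)(λ^(α−1) − λ^(−α/2−1)).

The general spectral form of the Piola stress (eigenvector dyads of the
Cauchy–Green tensors) is not materialized: the uniaxial deformation
gradient is diagonal, so the spectral sum collapses exactly to the scalar
expression above.  A finite-difference oracle on the uniaxial energy
ψ_uni(λ) = (2μ/α²)(2λ^(−α/2) + λ^α − 3) guards this reduction in the test
suite (relative agreement better than 1e−6 over λ ∈ [0.80, 1.05]).

The stiffness summary is the apparent Young's modulus E_app = 2μ(1+ν) = 3μ
(ν = 0.5 under incompressibility).  It equals the small-strain slope
dP_zz/dλ at λ = 1 for every admissible (μ, α).

Parameterization notes: |α| < 0.01 is rejected because the energy divides
by α² (the neo-Hookean-like regime is reached at α = 2, not α → 0); α may
be negative, as is common for brain-like tissues.  No multi-term Ogden,
compressibility, anisotropy, rate dependence or damage law is modeled;
cycle conditioning is handled as data (see below), not constitutively.

## Preprocessing of cyclic recordings

A recording is a triangular displacement protocol: three cycles to 15%
strain at 0.01 s⁻¹ by default.  Turning points are found on a
moving-median-smoothed displacement (window 5 samples, robust to sensor
jitter) and then refined to the raw extremum within the smoothing
neighborhood, because the median filter flattens the triangular extremum
and would otherwise bias the trough by a sample.  Detected cycle counts
that differ from the expected count raise an error carrying the detected
turning indices.

Loading and unloading of a cycle are converted to (λ, P_zz), linearly
interpolated onto a uniform λ grid over their common range, and averaged
pointwise; the average of the first cycle is the *unconditioned*, of the
third the *conditioned* response.  Averaging happens in stress–stretch
space (not raw signal space); for exact geometry the two are identical.
The averaging identity — symmetric multiplicative hysteresis cancels
exactly — is sharp only at grid nodes that coincide with sample
stretches; tests therefore use the sampling-aligned grid size exposed by
the simulator (`MechSimSpec.aligned_grid_size`, 151 nodes for the default
protocol), while the analysis default for real data is a 100-node grid.
The homogeneous-deformation assumption (frictionless slip at the platens)
is accepted as-is; no barreling correction is applied.

The per-sample scalar compared across conditions is the maximum |P_zz| of
the first loading phase.

## Calibration

(μ, α) are estimated by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) on the averaged curve,
minimizing χ² = Σ (P_zz − P_zz^model)².  Bounds encode μ ∈ (1e−3, 1e7) Pa
and the α-singularity: α is explored as two sub-problems [−50, −0.01] and
[0.01, 50], seeded from the multi-start grid α₀ ∈ {−20, −5, 2, 10} with
μ₀ = (small-strain secant slope)/3 clipped to bounds.  The objective is
genuinely multimodal in α (a clean α = 2 curve admits a secondary local
minimum near α ≈ 10), which is why a multi-start is required; the
reported fit is the best start, and the full start audit (initial guess,
final objective, convergence flag) is kept on the results object.
Reported fit quality: χ², RMSE = √(χ²/n), and R² = 1 − χ²/TSS (NaN for
constant data).  Headline values are fitted on the unconditioned (first
cycle) curve; conditioned fits are computed identically.  Per-condition
averaged curves are fitted rather than averaging per-replicate parameter
fits, which is known to distort nonlinear parameter estimates.
Uncertainty quantification (e.g. bootstrap CIs) on (μ, α) is not
implemented.

## Morphometry

Traced skeletons (SWC: nodes with radii, parent links forming a forest)
are interpreted as a union of capsules: each segment is a conical frustum
with linearly interpolated radius and spherical end caps.  The distance
from a punctum to the filament *surface* is the minimum over segments of
(point-to-segment distance − local radius), clamped at zero.  A punctum
counts as synaptic if its surface distance is ≤ 2.5 µm — the threshold is
inclusive, and 2.5 µm corresponds to the z-step interval of the image
stacks; it is exposed as a configuration value.  Counting is vectorized
over points × segments and is tested for exact agreement with a
per-segment scalar brute force.

Neuronal volume is the sum of frustum volumes with no overlap correction
at branch points (a deliberate simplification; branch-dense cells are
slightly over-counted).  Densities are reported both per 100 µm³ of
neuronal volume and per 100 µm of neurite length, with neither
normalization privileged.  Viability is 100·live/(live+dead) from
live/dead object counts.

## Calcium activity

Raw ROI fluorescence (10 Hz default) is normalized to ΔF/F₀ with F₀ the
10th percentile of the trace (percentile baselines are standard and make
the scores invariant to lamp gain: multiplying raw F by a constant
changes nothing).  The noise scale σ(t) and running baseline m(t) are
rolling medians over a 1000-frame window: σ is 1.4826 × the windowed
median absolute deviation about m(t), robust to the transients
themselves; traces shorter than the window fall back to a single global
estimate with a warning.

Event detection honors the three stated external-tool parameters
(signal-to-noise ratio 2.2, noise window 1000 frames, minimum activity
count 2) but is otherwise this package's own documented algorithm, since
the tool's internals are unpublished: an event *enters* where
ΔF/F − m(t) > 2.2 σ(t) and extends over the surrounding contiguous run
above half that threshold (hysteresis; a single exit threshold at the
peak level fragments the decaying tail).  Components shorter than 1 s are
discarded — the bound sits between the length of chance noise runs (a few
hundred ms at this SNR) and the seconds-long decay of a real transient —
and surviving events closer than 0.5 s are merged.  Transients decaying
much faster than ~0.5 s would be missed by this rule.  The threshold is
measured from the rolling median, not from zero: the percentile baseline
sits below the noise center, and thresholding raw ΔF/F would lower the
effective SNR from 2.2 to roughly 0.9.

Per-ROI scores: AUC (sum over events of the trapezoidal ΔF/F area above
zero, ΔF/F·s), amplitude (mean event-peak ΔF/F; a raw-units mode exists
but is never mixed within a run), and frequency (events/s).  ROIs with
fewer than two events are flagged inactive and excluded from group
scoring.  Detection is deterministic: identical trace and configuration
give an identical event list.

## Group statistics

One-way designs: Shapiro–Wilk per group at α = 0.05; if every group
passes, one-way ANOVA followed by Tukey–Kramer (or Holm–Šídák-adjusted
pairwise t tests when selected); if any group fails, Kruskal–Wallis
followed by Dunn's rank-based post hoc with tie correction and Bonferroni
adjustment (the adjustment is configurable; Bonferroni is the default
because no specific method is mandated).  Two-way (condition × day)
designs: two-way ANOVA with interaction (statsmodels OLS / anova_lm,
type-II sums of squares) followed by Tukey on the condition-day cells;
main effects and the interaction are all reported, and the post hoc is
not gated on the interaction.  Significance stars follow the four-level
convention (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).  Standard
test implementations (scipy, statsmodels) are called rather than
re-derived; Dunn's test is implemented here (z_ij from mean ranks with
tie-corrected variance) because no installed package provides it, and is
cross-checked against Kruskal–Wallis H = z² in the two-group case.
All-constant data short-circuit to a degenerate no-rejection result.

The router's calibration is verified by simulation: the empirical type-I
error of the routed omnibus under a 3-group normal null (n = 10 per
group) is 0.051 at 20 000 replicates; at the 2000-replicate problem size
used in the acceptance checks the binomial standard error is ±0.005, so
individual seeded runs scatter accordingly.

## Synthetic data

The generators define the conditions under which the pipeline is tested;
all randomness flows from one explicit seed per spec, and every generator
returns its ground truth with the data.

- **Mechanics** — triangular displacement at the study protocol (three
  cycles, 15% strain, 0.01 s⁻¹; 10 Hz sampling), force = A·P_zz from the
  analytic Ogden stress.  Hysteresis is multiplicative and symmetric
  (loading ×(1+η), unloading ×(1−η), default η = 0.1) so the averaging
  step recovers the baseline *exactly* — a sharp, falsifiable identity
  rather than an approximation; samples landing exactly on waveform
  knots carry the baseline value, because the two branches of a
  hysteresis loop meet at the turning points.  Conditioning is a single
  multiplicative softening of cycle 3 (default s = 0.85, Mullins-like),
  minimal structure to test unconditioned/conditioned bookkeeping.
  Stress noise is multiplicative Gaussian.  Rheometer inertia and
  friction artifacts are not simulated, so passing tests validate the
  analysis contract, not instrument physics.
- **Scenes** — a random-walk polyline with constant radius in a box;
  "inside" puncta are placed at uniform surface distance within the
  2.5 µm shell (adding segments can only shrink a distance, so the
  placement is guaranteed), "outside" puncta are uniform box draws beyond
  a 2.6 µm margin, leaving a deliberate gap so threshold arithmetic can
  never flip a label.
- **Calcium** — per-ROI homogeneous Poisson event times (default
  0.02 events/s over 300 s) snapped to the 10 Hz sampling grid (so the
  peak is actually sampled and the analytic per-event AUC = A·τ is
  attainable), exponential decay τ = 2 s, amplitudes uniform in 6–10
  noise sigmas, Gaussian noise of 0.02 ΔF/F on a constant baseline
  F₀ = 100.  Real recordings additionally contain drift, bleaching and
  correlated noise, which these traces do not emulate.
- **Groups** — labeled draws from named families (normal, exponential,
  lognormal) with a truth flag marking true nulls.

## Problem sizes and runtime

The acceptance computations use the sizes natural to the study protocol:
12-point (μ, α) oracle grids, 100-point fitting curves, 200 noisy-fit
replicates, 20 scenes × 1000 puncta, 50 ROIs × 300 s of traces, 2000
statistics replicates, and 3 conditions × 5 replicates end-to-end.  The
full test suite runs in well under a minute on one CPU; the acceptance
script in a few seconds.

## Known limitations

- Single-term Ogden only; no viscoelasticity, so the fitted parameters
  are specific to the 0.01 s⁻¹ loading rate.
- Frustum volumes ignore branch-point overlap.
- The calcium detector is a re-interpretation of an unpublished tool;
  only its three published parameters are contractual.
- No uncertainty quantification on fitted parameters.
- The CSV/SWC dialects are package conventions; instrument exports vary
  and may need the delimiter escape hatch or light reshaping.
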