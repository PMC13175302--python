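# neuroquant

Quantitative characterization of soft 3D neural tissue models — for
labs building hydrogel-based spinal-cord or brain cultures who need to
turn their instrument exports into comparable numbers: compression
stiffness, synapse density, viability, network activity, and the group
statistics that compare them across culture conditions and time points.

The package covers four analysis stages plus seeded synthetic data for
all of them:

1. **Mechanics** — cyclic unconfined-compression recordings are
   segmented into loading/unloading phases, converted to nominal stress
   P_zz = f_z/A and stretch λ = 1 + Δz/h, and phase-averaged into the
   unconditioned (cycle 1) and conditioned (cycle 3) hyperelastic
   responses.  The incompressible one-term modified Ogden model

       ψ = (2μ/α²)(λ₁^α + λ₂^α + λ₃^α − 3),
       P_zz(λ) = (2μ/α)(λ^(α−1) − λ^(−α/2−1))

   is calibrated by bounded multi-start nonlinear least squares, and the
   stiffness summary is the apparent Young's modulus **E_app = 3μ**
   (Poisson ratio 0.5 under incompressibility).
2. **Morphometry** — synaptic puncta within 2.5 µm of the traced
   neurite *surface* (capsule union over an SWC skeleton with radii),
   densities per 100 µm³ of neuronal volume and per 100 µm of neurite
   length, mean neurite lengths, and live/dead viability.
3. **Calcium activity** — ΔF/F₀ traces (10 Hz), robust rolling-noise
   event detection (SNR 2.2, 1000-frame noise window, minimum 2 events
   per active ROI), and per-ROI AUC / amplitude / frequency scores.
4. **Group statistics** — Shapiro–Wilk-routed comparisons: one-way
   ANOVA + Tukey–Kramer when every group is normal, Kruskal–Wallis +
   Dunn otherwise, Holm–Šídák pairwise tests on request, and two-way
   (condition × day) ANOVA + Tukey.

## Worked example

Simulate a cyclic compression experiment (three cycles to 15% strain at
0.01 s⁻¹) for a soft gel with shear modulus μ = 150 Pa and nonlinearity
α = −10, with 10% symmetric hysteresis and 5% stress noise, then run the
analysis pipeline on it:

```python
from neuroquant import OgdenModel, preprocess_recording
from neuroquant.synthetic import MechSimSpec, generate_cyclic_recording

spec = MechSimSpec(mu=150.0, alpha=-10.0, eta=0.1, noise=0.05, seed=42)
rec, truth = generate_cyclic_recording(spec)

out = preprocess_recording(rec, grid_size=spec.aligned_grid_size)
print(f"max |Pzz| (first loading cycle): {out['max_stress_pa']/1e3:.4f} kPa")

res = OgdenModel(out["unconditioned"]).fit()
print(res.summary())
```

which prints

```
max |Pzz| (first loading cycle): 0.1841 kPa
One-term modified Ogden fit (incompressible, uniaxial)
========================================================
n points                           151
curve label                 unconditioned
shear modulus mu [Pa]           149.6891
nonlinearity alpha [-]           -9.9862
apparent modulus E_app [Pa]     449.0674
chi^2 [Pa^2]                  1.0745e+03
RMSE [Pa]                     2.6676e+00
R^2 [-]                         0.996616
converged                         True
multi-starts                         4
```

The fit recovers the simulated truth (μ = 150 Pa, α = −10, E_app =
450 Pa) to a fraction of a percent despite the noise: the maximum
first-cycle stress of 0.18 kPa and the apparent modulus of ~450 Pa are
the two scalars a stiffness comparison across culture conditions would
feed into `neuroquant.group_stats.route_and_compare`.

The same objects are reachable from the shell through the `nq` CLI
(`nq simulate mech`, `nq mech preprocess`, `nq mech fit`,
`nq morpho density`, `nq calcium score`, `nq stats compare`); each
subcommand is a thin wrapper over the functions above.

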