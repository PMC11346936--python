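# cardiopiv

Micro-PIV cardiac flow and tissue mechanics for embryonic teleost hearts:
from time-lapse brightfield image sequences of a beating heart to
phase-averaged velocity fields, pressure drops across the atrioventricular
canal (AVC) and outflow tract (OFT), endocardial wall strain, and the
**Endocardial Work (EW)** metric that separates developmental stages of the
heart.

The package is written for experimental fluid-mechanics and developmental
biology groups that image embryonic/larval fish hearts (medaka, zebrafish) at
high frame rates and want a fully automated, non-invasive readout of cardiac
pressure and wall mechanics. Because such recordings are rarely archived, a
first-class synthetic phantom generator renders red-blood-corpuscle-seeded
image sequences with complete ground truth, so every stage is testable
without raw fish data.

## The analysis

1. **POD background removal.** The image time series is decomposed by
   singular value decomposition; the dominant modes carry the static
   background and are discarded, retaining the fluctuation modes of the
   moving red-blood-corpuscle (RBC) patterns.
2. **Ensemble phase-correlation PIV.** Three coarse-to-fine passes
   (96/48 px at 50 %, 64/32 at 50 %, 64/32 at 75 % overlap) of
   FFT cross-correlation with symmetric iterative window deformation
   (Blackman apodization, 3–6 iterations). Correlation planes from the same
   cardiac phase of every cycle are averaged before the three-point Gaussian
   sub-pixel peak fit; outliers fail the universal normalized-median test
   (3×3 neighborhood, threshold 2) and are replaced.
3. **Velocity reconstruction at the canals (∇·u = 0).** The narrow AVC/OFT
   is under-resolved by interrogation windows; its vectors are rebuilt from
   the conservation-of-mass principle.
4. **Rheology.** Hematocrit Ht follows from the RBC-pattern count of the
   average image autocorrelation, `Ht = 100·V_rbc·N_rbc / V_vol`, and blood
   viscosity from the Walburn–Schneck model
   `μ = C1·exp(C2·Ht)·exp(C4·TPMA/Ht²)·γ^(−C3·Ht)` at the cycle-peak wall
   shear rate γ.
5. **Pressure.** `∇P = −ρ(∂u/∂t + u·∇u) + μ∇²u`, reduced to the creeping-flow
   viscous term (Re ≪ 1, Wo ≪ 1), assembled with Compact–Richardson
   gradients and integrated by omnidirectional multi-path averaging until the
   residual falls below 1e-3; reported both in Pa and non-dimensionalized by
   HR·μ.
6. **Strain.** The endocardial wall is segmented from the |∇u|·|u| product
   field (90th percentile → Otsu → morphology); material points are advected
   from end-systole to build `F = I + ∇d`, and the Green–Lagrange tensor
   `E = ½(FᵀF − I)` gives the wall strain (mean of the three largest boundary
   values per phase).
7. **Whole-heart metrics.** HR from the Fourier transform of the velocity
   waveform; `Re = ρVd/μ`; `Wo = d√(ρω/μ)`; EF from the cylindrical ventricle
   model `Vol = (π/4)·L·D1·D2, D2 = D1`; and
   `EW = ∫ ΔP_AVC d(strain)` over the diastolic window (trapezoidal, Pa-%),
   classified as linear heart tube (< 100 Pa-%), looped chambers
   (< 300 Pa-%), or fully formed chambers (≥ 300 Pa-%).

## Worked example

Render a beating two-chamber phantom (circular atrium and ventricle joined by
a 9 μm canal, ±6 % wall dilation, 4 cycles at 400 frames/s) and run the full
pipeline against its ground truth:

```python
from cardiopiv.synthetic import PhantomSpec, _HeartModel, generate_phantom_heart
from cardiopiv.pipeline import PipelineConfig, run_pipeline

spec = PhantomSpec(n_cycles=4, period_s=0.2, noise_sigma=0.02, seed=11)
m = _HeartModel(spec)
stack, truth = generate_phantom_heart(spec)

cfg = PipelineConfig(
    passes=[(32, 16, 0.5), (24, 12, 0.5)],
    avc_upstream_um=(m.cx_a, m.cy), avc_downstream_um=(m.cx_v, m.cy),
    canal_strip_um=(m.cx_a + m.aa, m.cx_v - m.av, m.cy - m.w/2, m.cy + m.w/2),
    ventricle_roi_um=(m.cx_v - m.av, m.width_um, 0.0, m.height_um),
    reference_locus_um=(m.cx_v + m.av, m.cy),
    inlet_diameter_um=spec.canal_width_um,
    cycle_period_frames=spec.frames_per_cycle,
    outdir="phantom_run", seed=11)
manifest, results = run_pipeline(cfg, stack=stack)
s = results["summary"]
print(f"HR {s.hr_bpm:.1f} bpm | EF {s.ef_pct:.1f}% | EW {s.ew_pa_pct:.2f} Pa-% | {s.stage}")
```

This prints

```
HR 298.1 bpm | EF 34.1% | EW 8.39 Pa-% | linear
```

against prescribed truth HR = 300 bpm, EF = 30.3 % and a prescribed
ΔP–strain path area of 9.34 Pa-%: the heart rate is recovered within the
spectral resolution of the 4-cycle recording, the ejection fraction within
4 percentage points, and the endocardial work within 11 % — a low-EW
"linear-stage-like" phantom. Stage outputs (vector fields, ΔP series, the
pressure–strain loop, a one-row summary) are written as CSV under `outdir`
together with a JSON run manifest.

The same analysis is available from the shell:

```bash
cardiopiv fixture --config phantom.yaml --outdir fixture/   # phantom dataset
cardiopiv run     --config analysis.yaml                    # full pipeline
```

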