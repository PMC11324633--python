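# spectsub

Difference imaging for dual-injection SPECT: four subtraction strategies
inside OSEM reconstruction, with a digital liver phantom and quantitative
evaluation.

## The problem

In hepatic radioembolization, a Tc-99m-MAA safety scan maps where
microspheres will lodge. To quantify how a vasoconstricting drug shifts
that distribution toward tumors *within a single interventional session*,
half the tracer is injected and imaged, the drug is given, the second half
is injected, and a second SPECT is acquired. The second scan measures the
**sum** of both distributions; the clinically interesting quantity is the
**difference image** — the distribution added by the second injection —
which must be isolated by subtraction. SPECT subtraction is hard: counts
are low (≈1e6 per 10-minute scan), noise is high, resolution is poor.

`spectsub` is for imaging physicists who want to compare the four standard
ways of forming that difference image, d, from a baseline scan
y_pre and a combined scan y_post under a shared OSEM forward model A:

| method | principle | domain |
|---|---|---|
| image subtraction | d = OSEM(y_post) − OSEM(y_pre), negatives kept | image |
| projection subtraction | d = OSEM(max(y_post − y_pre, 0)) | projection |
| projection addition | d = OSEM(y_post) with b = y_pre as additive background: y_post ≈ A d + y_pre | projection |
| image addition | joint EM on (d, x_pre): y_post ≈ A d + A x_pre and y_pre ≈ A x_pre | image |

all against the *conventional* reference — OSEM of a separately acquired
scan of the difference distribution alone. Evaluation uses the activity
recovery coefficient ARC = 100·⟨a_est⟩/⟨a_true⟩, normalized background
noise, contrast, CNR = contrast/noise (Rose criterion: CNR ≳ 5 for
reliable detectability), and the tumor-to-nontumor ratio
T/N = ⟨a_tumor⟩/⟨a_bg⟩, each at the first OSEM iteration where every VOI's
ARC changes by <1 percentage point.

The bundled phantom is a parametric torso: elliptical-cylinder body,
ellipsoidal liver (~2.1 L), and two spherical tumors probing opposite
behaviors — a 30 mm tumor whose T/N doubles (2.00 → 4.00) and a 50 mm
tumor that depletes (5.00 → 1.00) — with 75 MBq per injection, 120
projections over 360°, attenuation, depth-dependent collimator blur
(FWHM = 4 mm + 0.05·depth) and Poisson noise. See `docs/methods.md` for
the model details and design choices.

## A worked example

```python
import spectsub as ss

cfg = ss.default_config("desk")               # 54x54x48 grid @ 9.6 mm
pre, post, diff = ss.build_phantom_pair(cfg)  # activity volumes, MBq/voxel
mu = ss.build_attenuation(cfg)
geom = ss.SystemGeometry()                    # 120 views, 10-min scan
model = ss.SystemModel(mu, geom)              # precomputed projector

f_pre = ss.ProjectionSet(model.forward(pre.values), geom.angles_deg)
f_post = ss.ProjectionSet(f_pre.counts + model.forward(diff.values),
                          geom.angles_deg)    # one physical acquisition
y_pre = ss.add_poisson_noise(f_pre, seed=1)
y_post = ss.add_poisson_noise(f_post, seed=2)

fit = ss.SPECTSubtraction(y_post, y_pre, model,
                          method="image_addition").fit(n_iterations=12,
                                                       n_subsets=8)
print(fit.summary())

masks = ss.build_voi_masks(cfg, erosion_voxels=2)
print(fit.metrics(masks, diff).query("iteration == 12").round(3))
```

prints

```
SPECT difference reconstruction
==================================
method:          image_addition
iterations:      12 (x 8 subsets)
grid:            (54, 54, 48) @ 9.6 mm
total activity:  74.871 MBq (difference image)
min voxel:       0.00000 MBq

 iteration        voi     arc  noise  contrast    cnr  tn_ratio
        12    tumor_1  76.351    NaN     2.049 11.549     3.049
        12    tumor_2 111.167    NaN     0.110  0.620     1.110
        12 background 100.153  0.177       NaN    NaN       NaN
```

Reading this: the reconstructed difference carries 74.9 of the true
75 MBq; the growing tumor recovers 76% of its true mean uptake (partial
volume at 30 mm) but stands out at CNR 11.5, comfortably detectable; the
depleted tumor correctly shows almost no contrast (T/N 1.11, its ARC is
measured against its background-level true mean); the joint reconstruction
keeps every voxel non-negative (min voxel 0).

Full comparisons and parameter sweeps run from the library
(`spectsub.experiments.run_default_comparison`, `run_sweep`,
`render_report`) or the CLI:

```sh
spect-subtract run --out results/default           # Table-style comparison
spect-subtract sweep --parameter total_activity --values 50,150,250 \
    --out results/activity
spect-subtract reconstruct --method imgadd --iterations 25 --seed 1 \
    --out results/volumes                          # NIfTI trace + provenance
```

## Layout

- `spectsub.phantom` — parametric torso phantom, VOI masks, sweeps
- `spectsub.system` — geometry, projector (attenuation + depth-dependent
  PSF, exact adjoint), count calibration, Poisson noise
- `spectsub.recon` — OSEM, the four strategies, `SPECTSubtraction` /
  `SPECTSubtractionResults`
- `spectsub.metrics` — ARC, noise, contrast, CNR, T/N, optimal-iteration
  rule, paired tests
- `spectsub.experiments` — end-to-end comparisons, sweeps, reports
- `spectsub.io` / `spectsub.cli` — YAML configs, NIfTI/HDF5, `spect-subtract`
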