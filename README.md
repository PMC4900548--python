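# cdtmorph

Template-based morphometry for high angular resolution diffusion MRI
(HARDI), aimed at group discrimination problems such as separating
Parkinson's-disease-like anatomy from controls.

Scalar diffusion summaries (FA from a single tensor) discard fiber
orientation and fail in crossing regions.  `cdtmorph` instead works with
the **ensemble average propagator (EAP)** — the displacement density
`P(r) = ∫ E(q) e^{−2πi q·r} dq`, with `E(q) = S(q)/S₀` — represented at
every voxel as a zero-mean Gaussian mixture over a shared dictionary of
axially symmetric diffusivity tensors:

    P(r) = Σ_k w_k N(r; 0, 2τ D_k),     D_k = (λ∥−λ⊥) u_k u_kᵀ + λ⊥ I.

The pipeline:

1. **EAP fields** — nonnegative least squares fits the per-voxel weights
   to the attenuations (`gmf.estimate_gmf`).
2. **Sharp template** — groupwise diffeomorphic registration of the
   control fields (voxel-wise closed-form L2 distance between mixtures,
   preservation-of-principal-direction re-orientation, log-det volume
   penalty) builds an unbiased intermediate template, which is then
   *projected* onto the set of warped real images: the final template is
   a deformed subject, not a blur (`template.build_template`).  The
   two-stage scheme costs O(N) registrations.
3. **CDT morphometry** — each subject's warp to the template yields the
   Cauchy deformation tensor `√(JJᵀ)` per ROI voxel: an SPD(3) strain
   measure that is identity under local rigid rotation
   (`spd.cdt_from_jacobian`).
4. **PGA + ν-SVM** — principal geodesic analysis (tangent-space PCA at
   voxel-wise Fréchet means, affine-invariant metric) reduces the
   6 × V-dimensional tensor features; a grid-searched ν-SVM with RBF
   kernel is scored leave-one-out, against an FA baseline
   (`classify`, `pipeline.run_study`).
5. **Localization** — a voxel-wise Hotelling T² in the tangent space at
   the pooled Fréchet mean, permutation-calibrated, maps the
   discriminative voxels (`spd.manifold_t_test`).

Everything is exercised end to end on synthetic HARDI phantoms
(64 directions, b = 0/1000 s/mm², Rician noise) with known ground truth
(`synthetic`).  See `docs/methods.md` for the model details, parameter
defaults and limitations.

## Worked example

Simulate a two-class population in which patients differ from controls
only by an in-place rotation of fiber orientations inside a small block
(a deliberately FA-invariant effect), then run the full study:

```python
import numpy as np
from cdtmorph import classify as cl, pipeline as pl, registration as reg
from cdtmorph import synthetic as syn

spec = syn.PhantomSpec(shape=(24, 24, 16), snr=20.0, seed=4, n_orient=12)
effect = syn.EffectSpec(roi_block=((9, 15), (9, 15), (6, 10)),
                        warp_amplitude=0.0, rotation_angle_deg=60.0)
subjects, labels = syn.make_two_class_population(8, 8, spec, effect,
                                                 seed=7, warp_amplitude=1.0)
report = pl.run_study([dwi for dwi, _ in subjects], labels,
                      effect.roi(spec.shape), dictionary=spec.dictionary(),
                      reg_config=reg.RegistrationConfig(n_iter=25, n_levels=2),
                      grid=cl.GridSpec(stride_factor=10),
                      outer_iters=1, run_fa=True, seed=1)
s = report.summary()
print(f"CDT : acc={s['cdt']['accuracy']:.3f} sens={s['cdt']['sensitivity']:.2f} "
      f"spec={s['cdt']['specificity']:.2f} at (r,g,nu)=({s['cdt']['r']},"
      f"{s['cdt']['g']:.3f},{s['cdt']['nu']:.3f})")
print(f"FA  : acc={s['fa']['accuracy']:.3f} sens={s['fa']['sensitivity']:.2f} "
      f"spec={s['fa']['specificity']:.2f}")
print(f"registrations: {s['n_registrations']}")
```

prints

```
CDT : acc=1.000 sens=1.00 spec=1.00 at (r,g,nu)=(5,0.161,0.001)
FA  : acc=0.688 sens=0.50 spec=0.88
registrations: 32
```

The CDT features separate the groups perfectly because the registration
sees the rotated orientations through the mixture distance and PPD
re-orientation, while FA — a rotation-invariant scalar — stays near
chance.  The 32 registrations are the O(N) budget: one outer template
iteration over 8 controls, 8 projection registrations, and 16
subject-to-template registrations.

The same workflow is available from the shell:

```bash
cdtmorph simulate --out data --n-ctrl 8 --n-pat 8 --seed 7
cdtmorph run-all --manifest data/manifest.tsv --roi data/roi.nii.gz --out results
```

which writes per-stage products (EAP fields, templates, deformations,
CDT volumes, PGA model, `report.json`, `table1.csv`, p-value maps) and
skips up-to-date stages on re-runs.

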