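# vertemorph

Statistical shape modelling and hexahedral mesh morphing for generating
finite-element (FE) models of the thoracolumbar spine.

Adult spinal deformity research needs patient-specific biomechanical
models, but building a structural (hexahedral) FE mesh for each patient by
hand is slow. `vertemorph` implements the pipeline that automates it:

1. **Align** a family of corresponding triangulated spine surfaces with
   Generalized Procrustes Alignment (rigid only — pose is nuisance,
   anatomy is signal).
2. **Learn** a statistical shape model (SSM) by PCA: with training shapes
   `X_i`, mean `μ = (1/n) Σ X_i` and covariance
   `Cov = (1/(n-1)) Σ (X_i − μ)(X_i − μ)ᵀ`, new shapes are

   `Shape = μ + Σᵢ √dᵢ · φᵢ · wᵢ`

   where `φᵢ, dᵢ` are eigenvectors/eigenvalues of `Cov` and `wᵢ` are
   weights in standard-deviation units.  Model quality is reported as the
   standard triad: compactness, leave-one-out generalization and
   specificity.
3. **Morph** a validated hexahedral template onto target surfaces with
   coherent-point-drift-style registration: the template is treated as
   Gaussian-mixture centroids, EM alternates soft correspondences (with an
   outlier class) with closed-form updates of a rigid part plus a
   motion-coherent displacement field; a multi-layer refinement loop
   repeats until the maximum point-to-correspondence distance falls below
   0.04 mm.  Intervertebral disc (IVD) templates carry annulus / nucleus /
   cartilage-endplate tissue sets whose proportions are controlled during
   morphing (nucleus at 40 % of disc volume, 25 % of the mid-height
   cross-section; cartilage endplates 0.7 mm thick).
4. **Transfer** the SSM deformation fields onto the hexahedral mean by
   closest-point correspondence, giving the hexahedral SSM
   `Shape = Hexahedral_Mean + DF · b`, from which a virtual cohort
   (5 modes × 7 SD levels = 16 807 instances) is sampled as coordinate
   files substitutable into one template INP.
5. **Validate and annotate** every instance: Gauss-point Jacobian
   determinants (an element with a non-positive determinant is invalid for
   FE analysis), aspect ratios and quad corner angles; spinopelvic
   sagittal-balance parameters (PI, PT, SS, LL, LL−PI, GT, RPV, RLL, LDI,
   RSA, TPA, SVA, Cobb) and the Global Alignment and Proportion (GAP)
   score, 0–13.

Everything also runs on built-in synthetic study conditions (planted-mode
shape families, a parametric spinopelvic landmark constellation, a
calibrated synthetic IVD template), so the full pipeline is testable
without patient data.

## Worked example

```python
import numpy as np
from vertemorph import align, hexssm, meshkit, metrics, ssm_tri

# synthetic cohort of corresponding spinopelvic constellations
shapes, registry = meshkit.make_spine_family(n=14, seed=3)
res = align.gpa(shapes)
report = ssm_tri.assessment_report(res.aligned, m=5, seed=0, n_specificity=200)

model = ssm_tri.fit_model(res.aligned, m=5)
hex_mean, node_reg = meshkit.make_spine_fe_template(model.mean_shape(), registry)
fields = hexssm.transfer_fields(model, model.mean_shape(), hex_mean,
                                rigid_align=False)
hm = hexssm.HexShapeModel(hex_mean, fields)

# personalize the hexahedral SSM against sagittal-balance targets
b_true = np.array([1.5, -1.0, 0.5, 0.0, 0.0])
p = metrics.measure_spinopelvic(hexssm.sample_hex(hm, b_true), node_reg)
b, achieved, resid = hexssm.personalize(
    hm, {"PI": p.pi, "PT": p.pt, "SS": p.ss, "LL": p.ll}, node_reg)
```

This prints (via the obvious `print` calls):

```
GPA converged in 3 iterations (mean movement 1.07e-07 mm)
compactness(5 modes) = 0.999
mode shares = [0.86, 0.116, 0.015, 0.008, 0.001]
generalization RMSE = 0.247 +/- 0.163 mm
target: PI 57.35, PT 46.54, SS 10.80, LL -45.21
personalized b = [1.514, -0.962, 0.318, -0.153, -1.352] residual 3.70e-13
achieved: {'PI': 57.35, 'PT': 46.54, 'SS': 10.8, 'LL': -45.21}
```

Reading: five modes capture 99.9 % of this synthetic family's variance,
with mode 1 dominating (86 %); leave-one-out reconstruction error is a
quarter of a millimetre; and a target sagittal profile (pelvic incidence /
tilt, sacral slope, lumbar lordosis, in degrees) is matched essentially
exactly by a bounded least-squares search over the mode weights — the
recovered instance reproduces all four parameters to two decimals.

A `vertemorph` command-line tool wraps the main workflows
(`convert`, `gpa`, `ssm fit|assess|cohort`, `morph`, `replace-coords`,
`validate`, `run`); `vertemorph run` executes the whole pipeline from a
YAML config and writes a reproducibility manifest.

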