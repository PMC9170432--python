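# histoseg

Histogram-analysis deformable-model segmentation for brain MRI lesions.

Early ischemic-stroke lesions are conspicuous on some MRI sequences
(hyperintense on FLAIR/DWI) but their boundaries are often blurred by
partial-volume effects and noise, which defeats classical deformable
models that stop the contour with image-gradient information.  `histoseg`
implements the alternative this package is built around: fit a Gaussian
mixture model (GMM) to the image intensity histogram by
expectation–maximization, then use the fitted mixture's statistics — not
gradients — as the force that drives and stops an implicit (level-set)
contour.  It is aimed at researchers in medical image analysis who want a
tested, seedable reference implementation with baselines and phantoms.

## The model

Intensity is modeled as a univariate mixture

```
p(x) = Σ_{l=1..L} π_l N(x; μ_l, σ_l²),   Σ_l π_l = 1,
```

fitted by EM on the image histogram (bin counts enter as sample weights,
so the binned fit is exact).  The E-step computes responsibilities
r_il = π_l N(x_i; μ_l, σ_l²) / Σ_k π_k N(x_i; μ_k, σ_k²); the M-step is
the standard responsibility-weighted update of (π, μ, σ²); the
log-likelihood is nondecreasing across iterations, which the test suite
asserts on every fit.  L can be fixed or chosen by BIC.

Segmentation turns the fit into a per-pixel speed

```
F(x) = log Σ_{l∈obj} p_l N(I(x); μ_l, s_l²) − log Σ_{l∈bg} p_l N(I(x); μ_l, s_l²),
```

positive where the object hypothesis (e.g. the brightest component for a
hyperintense lesion) dominates, and evolves a level set under
φ_t = −(F − ν κ)|∇φ| with upwind differencing, CFL-guarded explicit
stepping, periodic signed-distance reinitialization and a narrow band.
Classical parametric (Kass snake, "PD") and geometric (geodesic active
contour, "GD") deformable models are included as gradient-driven
baselines, along with evaluation metrics (sensitivity / specificity /
overall performance, Dice, rank-based ROC AUC) and a seeded brain-phantom
generator.  See `docs/methods.md` for the full model and numerics.

## Worked example

Segment a synthetic FLAIR-like phantom (three tissue classes at means
20 / 110 / 200, additive noise σ = 9, exact ground truth):

```python
import histoseg as hs

spec = hs.PhantomSpec(noise_sigma=9.0, seed=3)
phantom = hs.generate_phantom(spec)

seg = hs.VariableModelSegmenter(n_components=3).fit(phantom.image)
print("fitted mixture (pi, mu, sigma):")
for c in seg.gmm_.components:
    print(f"  pi={c.pi:.3f}  mu={c.mu:6.1f}  sigma={c.sigma2**0.5:5.2f}")
print(f"level-set iterations: {seg.n_iter_}  converged: {seg.converged_}")

counts = hs.confusion_from_masks(seg.mask_, phantom.truth_mask)
report = hs.performance_metrics(
    counts, dice=hs.dice_coefficient(seg.mask_, phantom.truth_mask))
print(f"sensitivity={report.sensitivity:.4f}  "
      f"specificity={report.specificity:.4f}  "
      f"overall={report.overall_performance:.4f}  dice={report.dice:.4f}")
```

Output:

```
fitted mixture (pi, mu, sigma):
  pi=0.498  mu=  20.0  sigma= 8.87
  pi=0.482  mu= 110.1  sigma= 9.06
  pi=0.020  mu= 199.3  sigma= 9.37
level-set iterations: 112  converged: True
sensitivity=1.0000  specificity=1.0000  overall=1.0000  dice=1.0000
```

The three recovered components are the background, parenchyma and lesion
classes (compare the generating means 20/110/200 and σ = 9); the lesion's
mixing weight 0.020 is its area fraction.  The level set converges in 112
iterations onto a mask that matches the ground truth voxel-for-voxel at
this noise level — sensitivity, specificity, overall performance and Dice
are all 1.0.

The same pipeline is scriptable from the shell:

```bash
histoseg simulate --n 5 --difficulty weak-edge --seed 1 -o suite/
histoseg segment --method proposed --object brightest \
    -i suite/phantom_000.png -o mask.png --seed 7
histoseg evaluate --predicted mask.png --truth suite/phantom_000_mask.png \
    -o metrics.csv
```

`--method gd` and `--method pd` run the baselines on the same inputs;
`fit-gmm` exports the fitted mixture as JSON, and `roc` computes the AUC
of a score/label CSV.

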