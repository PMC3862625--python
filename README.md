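# mvlle — multiview locally linear embedding for image retrieval

`mvlle` learns a single low-dimensional embedding from several feature
representations ("views") of one grayscale image collection — for
example gridded uniform-LBP texture histograms, dense-SIFT
bag-of-visual-words and intensity bag-of-visual-words.  It is aimed at
content-based retrieval of medical (or other textured grayscale) images,
where concatenating heterogeneous features into one long vector both
inflates dimensionality and treats informative and noisy features alike.

## The method

Each view `v` contributes a locally-linear-embedding alignment matrix
`L^v = (I − W^v)ᵀ(I − W^v)`, where row `i` of `W^v` holds the
coefficients (summing to 1) that best reconstruct sample `i` from its
K nearest neighbors in that view.  The embedding `Y` (N×d, orthonormal
columns) and a weight vector `α` on the V-simplex jointly minimize

    Σ_v α_v^r · tr(Yᵀ L^v Y),      α ≥ 0,  Σ_v α_v = 1,  r > 1,

by alternating two exact updates: an eigendecomposition of
`Σ_v α_v^r L^v` for `Y`, and the closed form
`α_v ∝ (1/t_v)^{1/(r−1)}` with `t_v = tr(Yᵀ L^v Y)` for the weights.
The exponent `r` interpolates between winner-take-all view selection
(`r → 1`) and uniform averaging (`r → ∞`); the objective is
non-increasing because each step is an exact conditional minimizer.
Defaults (`d=200, K=140, r=2.5`) follow the parameter study on a
~10⁴-radiograph collection.  See `docs/methods.md` for the full model
description, parameter discussion and limitations.

The package also ships the surrounding toolchain: the feature
extractors, single-view baselines (LLE, PCA, Laplacian eigenmaps), a
retrieval/diagnostic evaluation protocol (MAP@N, KNN-score ROC,
sensitivity/specificity/diagnostic odds ratio, F1), synthetic data
generators with known ground truth, and a CLI.

## Worked example

Three synthetic views of the same 2-D latent manifold — noise-free,
mildly noisy (σ=1) and heavily noisy (σ=5):

```python
import numpy as np
from mvlle import fit, gen_multiview_manifold, LatentManifoldSpec
from mvlle.synthetic import ViewSpec

spec = LatentManifoldSpec(
    n_samples=300, latent_dim=2,
    view_specs=(ViewSpec(ambient_dim=20, noise_sd=0.0),
                ViewSpec(ambient_dim=20, noise_sd=1.0),
                ViewSpec(ambient_dim=20, noise_sd=5.0)),
    seed=0)
views, latent = gen_multiview_manifold(spec)
result = fit(views, d=3, K=12, r=2.5)
print("view weights:", np.round(result.weights.alpha, 4))
print("objective:", [f"{v:.3e}" for v in result.objective_history[:4]], "...")
print("converged:", result.converged, "after", result.iterations, "iterations")
```

```
view weights: [0.9836 0.0141 0.0023]
objective: ['5.613e-02', '7.903e-03', '5.901e-03', '3.142e-03'] ...
converged: True after 9 iterations
```

The weight vector orders the views by informativeness: the noise-free
view receives 98% of the weight, the heavily corrupted one essentially
none, and the recorded objective decreases monotonically.

Diagnostic metrics work directly on TP/FP/FN/TN counts; on the published
contingency table (2129, 29, 185, 2285):

```python
from mvlle.evaluation import ContingencyTable, dor, f1, sensitivity
t = ContingencyTable(TP=2129, FP=29, FN=185, TN=2285)
print(round(dor(t), 2), round(sensitivity(t), 2), round(f1(t), 4))
# 906.76 0.92 0.9521
```

## Command line

```sh
mvlle simulate --kind texture --n-classes 2 --per-class 30 --out data/
mvlle extract-lbp --images data/ --grids 3,4 --out feats/f
mvlle build-dictionary --images data/ --kind sift --words 500 --out feats/dict.npz
mvlle extract-bow --images data/ --dictionary feats/dict.npz --grids 1,2 --out feats/f
mvlle embed-mlle --views feats/f_lbp_g3.npz --views feats/f_sift_g1.npz \
      --dim 10 --neighbors 15 --out emb.npz --report report.json
mvlle evaluate --embedding emb.npz --labels data/labels.csv --protocol map
mvlle pipeline-run --images data/ --out report.json
```

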