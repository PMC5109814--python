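# dynlogic

Dynamic-logic ("vague-to-crisp") mixture estimation: annealed mixture-model
EM with adaptive model structure, built to detect dim parametric shapes —
parabolic arcs and Gaussian blobs — whose signal amplitude lies *below* the
noise level, plus a generic product-Bernoulli formulation for feature-vector
data.

## The problem and the model

Classical detect-then-fit pipelines need a bright target: thresholding an
image whose signal-to-noise ratio is 1/3 leaves nothing to group. Dynamic
logic inverts the order. A set of top-down model components starts
deliberately *vague* — blob covariances spanning half the scene, Bernoulli
probabilities near 0.5 (the maximal-variance state) — and an association /
re-estimation loop sharpens them against the bottom-up data while a
*vagueness floor* on every scale parameter is annealed downward. Vague
models integrate evidence over large regions, so dim structure biases them
long before any single pixel is informative; by the time the floor reaches
the structure scale, the components have crisped onto the objects.

For observations `x_n` with weights `w_n` and components `m` with
proportions `r(m)` and conditional densities `l(n|m)`, the engine iterates

    f(m|n) = r(m) l(n|m) / Σ_m' r(m') l(n|m')          (associations)
    θ_m   ← θ_m + dt (θ_m^EM − θ_m)                    (damped M-step)
    r(m)   = Σ_n w_n f(m|n) / Σ_n w_n                  (proportions)

to maximize the total log-similarity `LL = Σ_n w_n ln Σ_m r(m) l(n|m)`,
stopping when the similarity stops increasing. `dt = 1` gives exact EM
steps; smaller `dt` emulates a continuous internal time. The per-iteration
increments of `LL` are logged as the run's "aesthetic emotion" trace.

Component families: uniform **clutter** (background), **blob** (bivariate
Gaussian), **parabola** (arc of half-extent U with an isotropic transverse
Gaussian profile, integrated by 64-node Gauss–Legendre quadrature), and
**bernoulli** (independent binary features, with an optional "dual model"
split into a vaguely-learned cognitive block and a lexicon-seeded crisp
language block). The mixture's *structure* adapts during the run: blobs are
born on residual mass, split, merge, convert into parabolas when the data
are thin and elongated, and are removed when they no longer pay their
penalized-similarity cost.

## Worked example

```python
import numpy as np
from dynlogic import DynamicLogicMixture

rng = np.random.default_rng(0)
pts = np.clip(np.vstack([
    rng.normal([3.0, 3.0], 0.5, size=(200, 2)),
    rng.normal([7.0, 7.0], 0.5, size=(200, 2)),
]), 0, 10)

est = DynamicLogicMixture(
    domain=(10.0, 10.0), floor_min=0.04, anneal_factor=0.85,
    convergence_tol=1e-7, settle_iterations=20, random_state=1,
).fit(pts)

print("converged:", est.converged_, "after", est.n_iter_, "iterations")
print("components:", est.report_.family_counts())
for c in est.components_:
    if c.family == "blob":
        print(f"  blob mean = {np.round(c.params['mean'], 3)}  r = {c.r:.3f}")
print("mean log-density:", round(est.score(pts), 4))
```

prints

```
converged: True after 55 iterations
components: {'clutter': 1, 'blob': 2}
  blob mean = [6.978 7.007]  r = 0.500
  blob mean = [2.951 3.012]  r = 0.500
mean log-density: -2.1412
```

The estimator started from one vague blob plus a clutter component; a
structural split was accepted mid-run, and the two crisped blobs recover the
true cluster centers (3, 3) and (7, 7) to within sampling error — and agree
with a standard EM fit of the same data to machine precision. `est.report_`
carries the full `RunReport` (per-iteration similarity, ΔKI trace,
structural events) and `est.predict_proba(X)` the association
probabilities.

The same machinery runs from the shell:

```sh
dynlogic fig3 --out out/              # sub-noise smile/frown scene + fit
dynlogic simulate --config scene.yaml --out scene/
dynlogic fit --scene scene/scene.pgm --config engine.yaml --out fit/
dynlogic report fit/report.json
```

`dynlogic fig3` simulates the package's reference experiment: three
parabolic arcs (two smiles, one frown) on a 64×64 raster with additive
Gaussian noise at amplitude SNR 1/3 — the signal peak is a third of the
noise standard deviation, invisible to the eye — and fits it starting from
clutter plus one vague blob with structural adaptation on.

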