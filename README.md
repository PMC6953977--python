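# hankelsrm

Robust learning of low-order linear dynamics from grossly corrupted
time-varying data, via **ℓq-regularized Schatten-p Hankel structured rank
minimization**, with two application pipelines built on top: continuous
prediction of behavioral/affective annotations from per-frame features, and
completion of missing trajectory entries for stitching fragmented tracks.

## Who this is for

Smoothly varying phenomena — continuous affect annotations (valence,
arousal, conflict intensity), object trajectories, any multichannel signal
with short memory — can be modeled as outputs of a low-order linear
time-invariant (LTI) system. The order of the minimal system generating a
trajectory equals the rank of its block-Hankel matrix, so learning
low-complexity dynamics becomes structured rank minimization. Real
measurements, however, carry gross but sparse corruptions (tracker
failures, annotator glitches) and missing stretches (occlusions), which
break least-squares-based Hankel methods.

## The model

Given observations `M ∈ R^{D×T}` (channels × time), an observation mask
`W`, and the block-Hankel map `H(·)` (optionally right-multiplied by an
orthonormal basis of the nullspace of the input Hankel matrix for
input–output problems), the package solves

    min_{N,L,E}  ‖N‖_Sp^p + λ ‖W ∘ E‖_q^q
    s.t.         M = L + E,   N = H(L)

with `p ∈ (0,1]` (Schatten p-norm of the Hankel surrogate — the nuclear
norm at `p = 1`, a tighter non-convex rank surrogate below it) and
`q ∈ (0,1] ∪ {2}` (ℓq sparsity surrogate for the corruption `E`; `q = 2`
is a plain Frobenius fit). The solver is an ADMM that alternates

* `E` — generalized q-shrinkage (elementwise prox of `α|·|^q`, closed
  three-case rule with a Newton root-finding step),
* `N` — generalized singular value p-shrinkage (the same shrinkage applied
  to the spectrum),
* `L` — closed form, after adding a proximal term in the semi-norm of
  `Q0 = L·I − H*H ⪰ 0` with `L = min{j,k}` that cancels the quadratic
  coupling through the Hankel map,

followed by dual and penalty updates. A scalable variant factorizes the
surrogate as `H(L) ≈ QR` with column-orthonormal `Q ∈ R^{M×K}` (Procrustes
update), replacing the full-size SVD with `K`-sized ones.

The estimated system order is the numerical rank of `N`; a deterministic
subspace realization (observability-matrix factorization, shift-invariance
least squares, then a linear solve for `B`, `D`, `x0`) turns the denoised
trajectory into a state-space model `x_{t+1} = A x_t + B u_t`,
`y_t = C x_t + D u_t` used for forecasting.

## Worked example

```python
import numpy as np
from hankelsrm import HankelRankMinimizer, make_instance, pearson_cor, rel_error

inst = make_instance(6, seed=3)          # order-6 signal, 20% gross corruption
est = HankelRankMinimizer(p=0.5, q=0.5, lam=0.3, r=50)
denoised = est.fit_transform(inst.y_tilde.T)

print(f"estimated order: {est.rank_}")
print(f"iterations:      {est.n_iter_} (converged={est.converged_})")
print(f"relative error:  {rel_error(inst.y, denoised.T):.4f}")
print(f"correlation:     {pearson_cor(inst.y, denoised.T):.4f}")
```

prints

```
estimated order: 4
iterations:      251 (converged=True)
relative error:  0.0910
correlation:     0.9961
```

i.e. from a trajectory in which every fifth sample (on average) is replaced
by noise at the signal's own standard deviation, the solver recovers the
clean signal to 9% relative error and 0.996 correlation, and identifies a
compact (order-4) system for it at this regularization; the estimator
exposes the low-rank/sparse split as `low_rank_` / `sparse_`.

`BehaviorPredictor` wraps the full prediction pipeline with the sklearn
`fit(X, y)` / `predict(X)` interface (features as system inputs,
annotations as system outputs); `stitch_tracklets` associates trajectory
fragments through a rank-ratio similarity and a generalized linear
assignment solved exactly by the Hungarian algorithm.

A command line mirrors the library:

```bash
hankelsrm solve traj.csv --p 0.5 --q 0.5 --lam-grid 1e-3 1 20 --out run/
hankelsrm predict --features u.csv --annotations y.csv --train-frac 0.6
hankelsrm track detections.csv --max-gap 30 --threshold 0.5
hankelsrm benchmark --orders 6,12,18 --reps 10
```

Every run writes a JSON manifest with flags, seeds and headline metrics.

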