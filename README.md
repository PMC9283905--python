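# eegmetric

Information-theoretic metric learning for EEG movement-intention decoding,
with interpretable per-channel importance maps.

## What this is for

Brain–machine interfaces need to decode *what* a person intends to do —
ideally before the movement starts — from scalp EEG, and researchers need to
know *which electrodes* carry that information. This package implements a
full pipeline for binary keypress-intention classification on 21-channel
10/20 recordings (200 Hz) with a self-paced paradigm: the keypress instant
is t = 0, and both the pre-movement window [-0.85, 0) s and the movement
window [0, 0.85) s are decoded.

The core is supervised **linear metric learning**: fitting a projection
A ∈ ℝ^{d×p} so that Euclidean distance in Y = XA reflects class membership.
Three learners are provided, all built on matrix-based Rényi entropy of
order α (computed from the spectrum of unit-trace kernel Gram matrices,
S_α = (1−α)^{-1} log Σᵢ λᵢ^α, with the joint formed via the Hadamard
product K_L ∘ K_Y):

* **CEML** — minimize the conditional entropy S_α(L | Y) subject to
  tr(AᵀA) = p;
* **EGML** — maximize the *entropy gap*
  EG_α(L; Y) = E_Π[S_α(L, Y_Π)] − S_α(L, Y), the joint-entropy surplus
  under random sample–label re-pairing; the gap closes at both scale
  extremes, so no trace constraint is needed and the scale of A
  self-tunes;
* **NCA** — maximize the expected soft leave-one-out nearest-neighbor
  accuracy Σᵢ Pᵢ, Pᵢⱼ = softmaxⱼ(−‖Axᵢ − Axⱼ‖²);

plus the identity (Euclidean) baseline. Classification uses a ν-SVM
(linear or Gaussian) with nested stratified 10-fold cross-validation over
(d_pc, p, ν, σ_SVM). Interpretability comes from the **importance** of
channel k in projected dimension j: with B = QA the PCA-composed map and
B̃ = UD its SVD-sorted form,

    importance(ch_k, j) = Σ_{i∈I_k} B̃²_ij / Σ_{i'} B̃²_i'j

where I_k are the feature columns of channel k — each dimension's
importance is a distribution over channels, renderable as a scalp
topography.

A synthetic-session generator produces continuous 21-channel recordings
with freely-timed labeled keypresses, readiness-potential-like frontal
deflections before onset, lateralized central deflections after it, and
white + 1/f background noise, so the whole stack is testable with known
ground truth. Sessions round-trip through the published FreeForm
MAT-dialect file layout.

## Worked example

```python
from eegmetric import (SynthConfig, generate_recording, extract_windows,
                       fourier_cartesian, TotalVariancePCA, EGML, HyperGrid,
                       compose_projection, sort_projection,
                       channel_importance, nested_cv)

rec = generate_recording(SynthConfig(n_trials=120, seed=0))
fm = fourier_cartesian(extract_windows(rec, "move"), band="0to5")
print(f"trials: {fm.X.shape[0]}, features: {fm.X.shape[1]}")

pca = TotalVariancePCA(n_components=20).fit(fm.X)
est = EGML(n_components=2, max_iter=300, random_state=0).fit(
    pca.transform(fm.X), fm.labels)
print(f"entropy gap at optimum: {est.objective_:.4f}")

imp = channel_importance(sort_projection(compose_projection(pca, est)),
                         fm.channel_index_map)
for ch, v in sorted(zip(imp.channels, imp.overall), key=lambda t: -t[1])[:5]:
    print(f"{ch}: {v:.3f}")

grid = HyperGrid(d_pc=(20,), p=(2,), nu=(0.3,), sigma_svm_scales=(0.5,))
res = nested_cv(fm.X, fm.labels, learner="egml", grid=grid, seed=0,
                learner_kwargs={"max_iter": 60, "n_perm": 5})
print(f"nested 10-fold accuracy: {res.mean:.3f} +/- {res.sd:.3f}")
```

Output:

```
trials: 120, features: 189
entropy gap at optimum: 0.6836
C4: 0.239
C3: 0.165
Fz: 0.111
F4: 0.110
A2: 0.071
nested 10-fold accuracy: 0.975 +/- 0.040
```

The 189 features are the "Cartesian" Fourier components ≤ 5 Hz (9 per
channel × 21 channels). The fitted entropy gap of 0.68 nats says the
observed label–projection pairing is that much more structured than random
re-pairings. The importance ranking recovers the planted effect: the
generator lateralizes the post-onset deflection across C3/C4, and those two
channels head the list with 40% of the total squared projection weight
between them. The nested cross-validated ν-SVM decodes the movement window
at 97.5% against a 50% chance level.

The same pipeline is scriptable from the shell:

```sh
eegmetric simulate --n-trials 120 --seed 0 --out session.mat
eegmetric cv --config experiment.yaml
eegmetric matrix --config experiment.yaml   # full learner × feature × window sweep
```

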