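# armik

Shared temporal basis functions for the inverse-kinematics problem of the
redundant human arm.

## The scientific problem

A planar drawing movement of the hand (an ellipse, a figure eight) lives in
a 3-dimensional task space, but the arm that produces it has 4 rotational
degrees of freedom — shoulder elevation, shoulder yaw, humeral rotation and
elbow flexion.  The inverse-kinematics (IK) problem — which joint
trajectory to use for a desired hand path — is therefore underdetermined.
One hypothesis from movement neuroscience is that the nervous system
sidesteps the redundancy by composing *both* spaces from the same small set
of periodic basis functions ("sources"): if the hand coordinates and the
joint angles are weighted, time-shifted superpositions of shared sources,
the task-to-joint transform reduces to simple algebra on the mixing
parameters.  The joint space is best expressed in *absolute* (external,
gravity-fixed) segment angles — elevation and yaw of the upper arm (θ, η)
and of the forearm (β, α) — rather than anatomical angles (θ, η, humeral
rotation ζ, elbow flexion φ).

`armik` implements that analysis chain end to end for researchers in
computational motor control:

* a 4-DOF two-link arm model with both representations, their conversions,
  forward kinematics and a numeric Jacobian, plus sphere-fit joint-centre
  estimation and joint-angle extraction from marker data;
* **FADA-style anechoic demixing**: each channel of a cycle-normalized
  trial is modelled as

      x_m(t) = Σ_p c_mp · s_p((t − τ_mp) mod P) + mean_m + residual,

  with real unit-norm sources s_p, signed weights c_mp and circular delays
  τ_mp, estimated in the Fourier domain by non-negative factorization of
  the squared coefficient magnitudes followed by alternating exact
  least-squares updates of (weights, delays) and source coefficients;
* the **shared-basis IK transform**: on the cycle-locked harmonic grid the
  task mixture is `F[x](ξ) = A(ξ)·F[s](ξ)` with the symbol matrix
  `A_ij(ξ) = a_ij·e^(−2πi τ_ij ξ)`; wherever `det A(ξ) ≠ 0` the system is
  inverted per harmonic and the joint cycles are re-composed as
  `q_i(t) = Σ_j β_ij s_j(t − τ̃_ij)`;
* evaluation statistics (similarity index = maximal circular normalized
  cross-correlation, sign test, balanced nested mixed ANOVA,
  reconstruction accuracy `1 − ‖x_rec − x0‖²_F / ‖x0 − x̄0‖²_F`);
* circular phase-shift statistics and a phase-lock detector for the
  coordination structure of the fitted delays;
* a synthetic-trial generator with known ground truth, so every stage has
  a closed-loop test bed;
* a `click` CLI (`armik simulate|preprocess|decompose|compare|ik|phase|run-all`)
  orchestrating the stages with seeded, reproducible runs.

The demixing and IK stages are written as scikit-learn-style estimators
(`AnechoicDemixing` with `fit`/`transform`/`inverse_transform`,
`SharedBasisIK` with `fit`/`predict`), so they compose with sklearn
pipelines and model selection.

## Worked example

Blind recovery of a known anechoic mixture (7 channels built from 3
sources with random signed weights, full-circle delays, per-cycle jitter
and 20 dB measurement noise), followed by the exact shared-basis IK round
trip:

```python
import numpy as np
from armik.synthetic_data import (
    generate_sources, mix_channels, dominant_mixture_weights,
)
from armik.fada import AnechoicDemixing, align_sources
from armik.ik_transform import build_symbol_matrix, invert_mixture, task_to_joint_full

# --- demix a noisy 10-cycle trial and compare with the generating sources
seed = 9
rng = np.random.default_rng(seed)
S = generate_sources(3, 200, seed=seed)
W = dominant_mixture_weights(7, 3, rng)
D = rng.uniform(0, 200, (7, 3))
X = np.stack([mix_channels(S, W * (1 + 0.05 * rng.standard_normal(W.shape)),
                           np.mod(D + 2 * rng.standard_normal(D.shape), 200))
              for _ in range(10)])
X += rng.standard_normal(X.shape) * np.sqrt(np.var(X) / 100)  # SNR 20 dB
est = AnechoicDemixing(random_state=seed).fit(X)
aligned = align_sources(est.to_source_set(), S)
print("mean residual fraction:", round(float(est.residual_fraction_.mean()), 3))
print("aligned source correlations:",
      np.round([np.corrcoef(aligned.sources[i], S[i])[0, 1] for i in range(3)], 3))

# --- shared-basis IK: invert a known task mixture, re-compose the joints
rng = np.random.default_rng(0)
S = generate_sources(3, 200, seed=5)
A, tau = rng.uniform(0.4, 1.0, (3, 3)), rng.uniform(0, 200, (3, 3))
beta, taub = rng.uniform(0.3, 0.8, (4, 3)), rng.uniform(0, 200, (4, 3))
x = mix_channels(S, A, tau)
sm = build_symbol_matrix(A, tau, K=10, P=200)
s_hat = invert_mixture(x, sm)
print("IK source recovery:", np.round([np.corrcoef(s_hat[i], S[i])[0, 1] for i in range(3)], 6))
q = task_to_joint_full(x, sm, beta, taub)
print("IK joint RMSE (rad): %.2e" % np.sqrt(np.mean((q - mix_channels(S, beta, taub)) ** 2)))
```

prints

```
mean residual fraction: 0.015
aligned source correlations: [0.989 0.943 0.986]
IK source recovery: [1. 1. 1.]
IK joint RMSE (rad): 7.74e-17
```

— the demixing explains the noisy channels down to roughly the noise floor
and recovers the generating waveforms; and when the mixing parameters are
known, the per-harmonic inversion reproduces sources and joint cycles to
machine precision.  A full multi-stage run:

```bash
armik run-all --seed 1 --out runs/demo
```

writes trial TSVs, fitted source sets, the absolute-vs-anatomical
correlation-difference table with its sign test, IK transfer accuracies
and the phase-shift/lock report, plus a manifest with seeds and timings.

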