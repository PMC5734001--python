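# sprtbci

Fast, reliable single-trial decisions for two-class motor-imagery
brain-computer interfaces (BCI): projective-power feature extraction by
generalized eigendecomposition, followed by a truncated sequential
probability ratio test (SPRT) whose thresholds are derived from a target
expected stopping time.

## Who this is for

Researchers working with cued left- vs right-hand motor-imagery EEG
(e.g. Graz-style recordings from channels C3/C4) who want a classifier that
accumulates evidence over time and exposes an explicit trade-off between
decision speed and error rate, plus a synthetic ERD/ERS generator so the
whole pipeline can be developed and tested without any recordings.

## The method

**Features.** For each channel, windowed signal vectors `x` from the two
classes define autocorrelation matrices `R_k = X_k X_k' / N_k`. A unit-norm
temporal filter `u` extremizes the ratio of mean projected powers

```
F(u) = (u' R_L u) / (u' R_R u),
```

solved by simultaneous diagonalization `T' R_L T = diag(λ), T' R_R T = I`;
`F` ranges over `[λ_M, λ_1]` and the extremal filters are the first/last
columns of `T`. The branch with the larger of `λ_1` and `1/λ_M` is kept.
The squared projections of each 1 s sliding window of C3 and C4 onto their
own bases form the feature vector `z_i = [e_C3, e_C4]`.

**Sequential test.** With per-segment-index Gaussian class models
`g_ki = N(m_ki, S_ki)`, the segment log probability ratio is

```
J_i = 1/2 [ log|S_Ri|/|S_Li| + D²(z_i, m_Ri) − D²(z_i, m_Li) ],
```

and the trial evidence is `L_q = Σ J_i`. Instead of fixing error rates, the
two thresholds come from a target expected stopping segment count `q_E`:
`ξ_L = Σ_{i≤q_E} E[J_i|L]`, `ξ_R = Σ_{i≤q_E} E[J_i|R]` (the expectations
have closed forms equal to ± the Gaussian Kullback–Leibler divergences).
The test decides L when `L_q ≥ ξ_L`, R when `L_q ≤ ξ_R`, and is truncated
at `q = q_E` by the sign of `L_q`. Wald's inequalities
`p(L|R) ≤ 1/η_L`, `p(R|L) ≤ η_R` bound the unforced error rates.
`q_E` can be swept to optimize accuracy, Wolpaw mutual information
`MI(p) = 1 + p log₂p + (1−p) log₂(1−p)`, its steepness `MI(t)/(t − 3 s)`,
or mean decision time.

## Worked example

```python
import numpy as np
from sprtbci import SPRTClassifier, SyntheticConfig, generate_dataset, tenfold_cv

epochs, truth = generate_dataset(SyntheticConfig(seed=3))   # 140 trials, C3/C4
report = tenfold_cv(epochs, n_folds=10, seed=0)
print(f"accuracy {report.accuracy:.3f}  MI {report.mi_bits:.3f} bits  "
      f"mean decision time {report.mean_decision_time:.2f} s")

clf = SPRTClassifier(q_e=6, random_state=0).fit(epochs)
path = clf.decision_paths(epochs)[0]
print(path.decision, path.stop_segment, f"{path.stop_time:.2f}s", path.forced)
```

prints

```
accuracy 0.893  MI 0.509 bits  mean decision time 5.60 s
L 3 4.50s False
```

i.e. the full pipeline decodes the planted contralateral mu/beta power
suppression at 89.3% in ten-fold cross-validation (0.509 bits per trial),
and with `q_E = 6` the first trial crossed the upper threshold on the third
post-cue segment (window ending 4.5 s into the trial, 1.5 s after the cue).

The same pipeline is available from the shell:

```
sprtbci simulate --config sim.yml --out data/
sprtbci fit --train data/ --model-out model.json
sprtbci decide --model model.json --data data/ --qe 6
sprtbci evaluate --data data/ --folds 10 --seed 1 --report report.json
sprtbci sweep --data data/ --criterion smi --out curve.csv
```

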