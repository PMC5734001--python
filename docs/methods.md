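# Methods

## Model and procedure

The package classifies epoched two-class (left vs right hand) motor-imagery
EEG in two stages.

**Projective-power features.** Each trial is cut into overlapping windows
(default 1 s window, 0.25 s step; a segment is stamped by its window-end
time, the earliest moment a causal decoder could have used it). For one
channel, the class-`k` training windows form `X_k`, and
`R_k = X_k X_k' / N_k` is the average outer product. The temporal filter
`u` (unit norm) extremizes `F(u) = u'R_L u / u'R_R u`. The solver whitens
`R_R` and symmetrically diagonalizes the pair (LAPACK generalized
symmetric-definite eigenproblem), giving `T` with `T'R_L T = diag(λ)`,
`T'R_R T = I`, `λ` sorted descending. `F` is scale-invariant and ranges over
`[λ_M, λ_1]`; the first column of `T` attains the maximum and the last the
minimum. The branch kept is `max` when `λ_1 ≥ 1/λ_M`, else `min` — i.e. the
side on which the class power ratio is more extreme. The per-window feature
is the squared projection on the channel's own base; C3 and C4 are stacked
into `z_i = [e_C3, e_C4]` (nonnegative, signal-units²).

**Sequential classification.** Features at segment index `i` are modelled
as class-conditional Gaussians fitted independently per index (the rhythm
is nonstationary over the trial). The per-segment log probability ratio
`J_i` (positive favours L) accumulates into `L_q = Σ_{i≤q} J_i`; segments
are treated as independent, a deliberate simplification that overlapping
windows violate in practice — the thresholds absorb the resulting optimism
because they are expressed in the same (mis)calibrated units. The
class-conditional expectations `E[J_i|L] = KL(g_L‖g_R) ≥ 0` and
`E[J_i|R] = −KL(g_R‖g_L) ≤ 0` have closed forms; partial sums up to a
target expected stopping segment count `q_E` define the thresholds
`ξ_L, ξ_R`. The test decides at the first boundary crossing and is
truncated at `q_E` by the sign of `L_{q_E}`. The decision stage runs on the
post-cue segments only (index 1 = first window fully after the cue), so
`q_E` counts task segments and decision times are cue-relative.

The expected-stopping-time relation implemented is the printed form

```
E(q|L) = inf_n { Σ E[J_i|L] ≥ (1−η_R)·log η_L + η_R·log η_R }
E(q|R) = inf_n { Σ E[J_i|R] ≤ (1−1/η_L)·log η_R + (1/η_L)·log η_L }
```

This mixes threshold symbols into the weights where the classical
expected-sample-size identity would use the error probabilities
(`α log B + (1−α) log A` style); the source formulation is kept verbatim
rather than silently substituting the textbook expression, and the two
agree in the small-error regime the method operates in.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | 1.0 s | projective-base length; also the model's window |
| `step` | 0.25 s | segment stride ("with overlap"); exposed, not prescribed |
| `ridge` | `1e-6·tr(R_R)/M` | diagonal loading of both `R_k`; raise it (≈ the per-sample noise power) when the window dimension is large relative to the per-class segment count, where the raw covariance ratio overfits |
| `shrinkage` | 0.05 | covariance shrinkage `(1−γ)S + γ(trS/2)I` per (index, class) |
| `transform` | `raw` | Gaussianity assumed directly on power features; `log` (`log(z+ε)`, `ε = 1e−12·mean power`) available since power is right-skewed |
| `q_e` / `criterion` | all post-cue segments / off | fixed stopping target, or grid search by 5-fold internal CV on the training split (accuracy, MI, SMI, or mean decision time subject to an accuracy floor, default 0.7) |
| `tie_policy` | `random` (seeded) | `L_{q_E} = 0` is undefined by the strict-inequality truncation rule; alternative `undecided` counts as an error |
| `train_window` | `post_cue` | which segments populate `X_k`; the discriminative task period (configurable to `all`) |

Natural logarithms are used throughout; decisions are base-invariant
because thresholds and evidence share the base. `N_k` counts training
*segments* (with sliding windows the segment count is the natural analogue
of a per-trial window count). Exact ties `λ_1 = 1/λ_M` go to the max
branch; basis sign is fixed by making the first non-negligible component
positive, so bases are reproducible across eigensolvers.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults emulate a 9 s cued trial (3 s preparation,
128 Hz, 70 trials per class, channels C3/C4): band-limited Gaussian mu
(8–13 Hz) and beta (18–30 Hz) rhythms whose post-cue amplitude is scaled by
a class/channel/band `erd_depth` factor through a 0.5 s raised-cosine ramp,
lognormal trial-to-trial amplitude variability (CV 0.25), and white
broadband noise (σ = 1; a 1/f option exists). Default depths plant
contralateral desynchronization (mu 0.5, beta 0.7). No published SNR or
rhythm amplitude exists for this setting; the defaults were chosen once for
a mid-difficulty regime (end-of-trial cross-validated accuracy ≈ 85–90%)
and are otherwise arbitrary.

`phase_locking` mixes a fraction of each rhythm's amplitude from a
trial-invariant waveform built from harmonics of `1/template_period`
(default 0.25 s, commensurate with the default segment step). Rationale: a
stationary random-phase rhythm has a rotation-degenerate window covariance
(sliding windows spread its power across the whole band subspace), so no
single "planted direction" exists for a ground-truth recovery check. With
part of the rhythm reproducible across trials and step-commensurate, the
pooled segment covariance acquires a dominant eigenvector and recovery
becomes well-posed. The default is 0 (induced rhythms are not phase-locked
to the cue); recovery tests use 0.9. Trials draw from streams keyed by
(seed, class, within-class index), so trial content survives reordering.

Not emulated: ocular/muscle artifacts, electrode drift, volume conduction,
inter-channel correlation of the rhythms, nonstationarity across a session.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative model, not decoding performance on real recordings.

## Numerical choices and degenerate inputs

- GEVD failures (singular `R_R` beyond the ridge) raise advising a larger
  ridge; `λ_M ≤ 0` (class matrix not PD on the span) is rejected.
- Covariances are validated SPD after shrinkage; zero-variance features and
  singular fits at `γ = 0` raise with the remedy named.
- An exactly zero truncation statistic falls to the tie policy; in the
  per-time sign classifier of `time_courses` it scores half credit (the
  expectation of a fair tie-break).
- Expected stopping times that never cross within the available segments
  return `inf` with a warning rather than raising.
- Model documents serialize floats at 17 significant digits and the csv_dir
  container is written `%.17g` / parsed with round-trip precision, so both
  round-trip bit-exactly.
- Grid ties in the stopping-time sweep go to the smallest `q_E`; the
  `mean_decision_time` criterion falls back to the accuracy optimum (with a
  warning) when no grid point reaches the floor.

## Evaluation protocol

Stratified k-fold (default 10) cross-validation assigns folds per class by
round-robin after a seeded shuffle and refits the entire pipeline within
every training split; a fingerprint of the fitted bases and Gaussian
parameters is recorded per fold so leakage is testable. Reported accuracy
counts forced decisions (truncation always yields a decision); the forced
fraction is reported separately, and `undecided` ties score as errors. MI
is the two-class Wolpaw transform of the fold-averaged accuracy; SMI uses
the preparation-period offset (default 3 s, configurable) and is undefined
within 0.5 s of it; mean decision time is the mean window-end time of the
stopping segment minus the cue time (origin configurable).

The sequential-Bayesian baseline is a reconstruction: flat-prior cumulative
posterior odds (identical to the evidence trace) read at a fixed decision
time chosen on the training split as the segment of peak mean posterior
confidence in the true class. The fixed-time baselines are a quadratic
discriminant built from the per-class (mean, covariance) and a
pooled-covariance LDA (scikit-learn).

## Known limitations

- Two channels and two classes only; no multiway sequential testing.
- The independence-across-segments assumption makes the nominal Wald error
  bounds optimistic on strongly overlapping segments (they are exact in the
  package's own Monte-Carlo checks, which draw independent segments).
- The per-index Gaussian models need enough trials per class per fold;
  heavy shrinkage is the only guard at very small n.
- On real data the raw covariance-ratio objective is prone to overfitting
  when `window samples / training segments` is not small; use the ridge.
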