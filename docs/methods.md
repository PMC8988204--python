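# Methods

`canopynet` implements a pipeline for predicting wheat grain yield (kg/ha)
and grain protein content (GPC, %) simultaneously from near-daily canopy
trait time series, together with a synthetic field-trial generator that
makes every stage testable without access to a real phenotyping dataset.
This note records the model, the generator's assumptions, the parameters
that matter, and the design choices made where the design was genuinely
open.

## The prediction problem

Each experimental plot is observed on up to 89 days after sowing
(DAS 107–195) by a proximal-sensing platform that yields fused 3D +
four-band (B, G, R, NIR) point clouds. From each cloud eight plot-level
traits are extracted:

* spectral: GNDVI = (NIR−G)/(NIR+G), CVI = (NIR/G)(R/G),
  NCPI = (R−B)/(R+B), MCARI = ((NIR−R) − 0.2(NIR−G))(NIR/R), each the
  per-point value averaged over the plot;
* structural: mean point height Hmean, 99th-percentile height H99 (mm),
  projected leaf area PLA (occupied xy grid cells × cell area, m²), and
  canopy volume (occupied voxels × voxel volume, m³).

A trait's season is a vector {x₁₀₇, …, x₁₉₅}. Missing days are filled by
piecewise-linear interpolation (constant fill at the window edges, so no
trend is extrapolated). Targets — and, in this implementation, the trait
channels as well — are min–max normalized to [0, 1] using statistics of
the original (non-augmented) examples only. Normalizing features is our
own addition: raw trait scales span four orders of magnitude (0.3 for
NCPI vs ~700 mm for Hmean), which is untrainable at the protocol's fixed
learning rate; a config flag disables it.

## Networks

Four topologies, named input-count–to–output-count:

* **one_to_one / one_to_two** — one trait vector → three hidden layers of
  16 units → one linear head (yield *or* GPC) or two heads (both).
* **two_to_one / two_to_two** — two traits, each encoded to 16 units by an
  interchangeable extractor, concatenated to 32, one further 16-unit
  hidden layer, then one or two linear heads.

Extractors: FC (dense 89→16), vanilla RNN and LSTM (16 units, last hidden
state), 1-D CNN (16 filters, kernel 3, 'same' padding, global average
pooling), and a temporal-attention module: an LSTM with 5 units returns
the full 89×5 feature sequence; a parallel line transposes to channels ×
time, applies a per-channel dense map over the time axis, normalizes with
a softmax along time, transposes back, and multiplies the two lines
elementwise. The softmax weights, averaged over the five channels, are
the per-day importance profile. Softmax normalization is a design choice
(it gives the weights a %-per-day reading and makes profiles comparable
across models); a flag can replace it with a sigmoid. Per-channel (rather
than channel-shared) attention maps are another open choice; profiles are
reported channel-averaged either way. In dual-input models the branch
extractors are untied.

Hidden activations are ReLU, heads linear, dropout 0.1 after every hidden
layer. The multitask loss is Eq.-style weighted MAE on the normalized
scale, `λ_gpc·MAE_GPC + λ_yield·MAE_yield` with λ summing to 1 and 0.5/0.5
by default.

Training: Adam (lr 0.001), batch 32, early stopping on validation loss
(default patience 20, max 500 epochs) with best-weight restoration, on an
80/10/10 random split. All randomness — weight init, shuffling, dropout —
is driven by explicit seeds; two runs with the same seeds are
bit-identical.

The networks are built on a small float64 NumPy reverse-mode autodiff
engine written for this package (`canopynet.nn`), with fused hand-written
backpropagation-through-time for the recurrent layers. Gradient
correctness is checked against central finite differences in the test
suite.

## The synthetic trial

The generator emulates a 120-variety × 2-nitrogen (240 vs 0 kg/ha) ×
2-replication split-plot trial (480 plots). Each plot receives a latent
state: maximum height h_max ~ N(0.9 m, 0.1), logistic growth rate
~ N(0.12/d, 0.02), mid-growth date ~ N(135, 5) DAS, anthesis ~ N(160, 3)
DAS, senescence rate ~ N(0.08/d, 0.02), vigor ~ N(1, 0.15) — all drawn
per variety, with a 5 % plot-level vigor jitter — and a plot-level
nitrogen multiplier n_effect ~ N(1.0, 0.08) under control or N(0.7, 0.08)
under deficiency.

Structural traits rise logistically to a plateau ∝ h_max·n_effect·vigor.
Spectral indices rise logistically and decay exponentially after anthesis;
their amplitude scales as n_effect·√vigor, reflecting the ~linear response
of chlorophyll-driven indices to nitrogen status — this also makes
(h_max, n_effect, vigor) jointly identifiable from a structural plus a
spectral trait, which is what lets the fusion models recover the targets.
Observation noise is multiplicative-plus-additive Gaussian, by default 3 %
of each trait's dynamic range. Structural traits are clipped at zero;
indices are not. Each plot keeps 51 or 53 observed days (alternating),
always including DAS 107 and 195.

Targets:

```
yield = a0 + a1·h_max·n_effect + a2·vigor·(195 − t_anthesis) + ε_y
gpc   = b0 + b1·n_effect − b2·(yield − μ_y)/σ_y + ε_p
```

with a = (300, 5500, 30), ε_y ~ N(0, 250 kg/ha), b = (5.5, 8.0, 1.5),
(μ_y, σ_y) = (5400, 1500) and ε_p ~ N(0, 0.3 %). Defaults give yields of
roughly 3 200–8 300 kg/ha and GPC of 10–14.7 %, a 1–2 point GPC response
to nitrogen, and a within-nitrogen yield–GPC correlation near −0.5 — the
classic protein dilution trade-off. All coefficients are config fields;
the spans were sized to typical winter-wheat trials and the noise terms so
that the trait-explainable variance ceiling is ~0.85–0.9 R² per target.

What the generator does **not** emulate: weather and management
covariates, spatial field autocorrelation between neighboring plots,
sensor-specific artifacts (occlusion, registration error), or
variety-by-nitrogen interaction beyond the multiplicative n_effect.
Passing tests therefore demonstrate that the pipeline recovers signal
with the planted statistical structure, not that a particular accuracy
will be attained on real trials.

A probe configuration (`planted_postanthesis_config`) freezes every latent
parameter except the anthesis date. All plots then share identical
pre-anthesis curves; yield and GPC vary only through anthesis timing,
which spectral indices reveal through the onset of their post-anthesis
decline. It is used to verify that the attention extractor concentrates
importance on post-anthesis days when that is where the signal lives.

## Augmentation

The prepared set is grown from 480 to 1 000 examples. Each new example
copies a random original and applies one of: jitter (Gaussian noise with
sd = 3 % of the per-trait sd of that example), scale (whole matrix ×
U(0.9, 1.1)), or resample (keep a random 60 % of days, re-interpolate).
Both normalized targets are then perturbed by a truncated
N(0, (0.05/3)²) restricted to [−0.05, 0.05]; a flag switches to
U(−0.05, 0.05). Augmentation runs *after* target normalization so the
±0.05 perturbation is meaningful on the [0, 1] scale. The jitter
fraction, scale range and keep fraction are package defaults chosen small
enough to preserve the trait dynamics; all are configurable. Augmented
copies may fall into any split by default; `force_originals_in_test`
restricts the test split to originals for leakage-free evaluation.

## Evaluation and importance analysis

R², RMSE and rRMSE (= RMSE/ȳ·100 %) are computed after denormalizing
predictions, so RMSE is in kg/ha and GPC points. Model comparisons train
each configuration with several shared seeds (default 5) and report
mean ± sd with a per-target rank — single training runs of these small
stochastic networks are not stable enough to rank on.

Attention profiles average the softmax day-weights over the test split
and scale to percent (each profile sums to 100 %). The pre/post-anthesis
summary splits the profile at DAS 160 by default, matching the
generator's mean anthesis date; it is a parameter.

## Problem sizes used by the test suite

The heavier experiments in the suite use: the full 480-plot default
design augmented to 1 000 examples for the recovery, fusion-benefit and
loss-weight experiments (3–5 seeds each, early stopping with patience
25–30 within 300–500 epochs); and a 240-plot single-nitrogen trial for
the planted post-anthesis attention probe (5 seeds, patience 20 within
150 epochs). The signal-recovery experiment uses the default design with
observation noise halved (its stated low-noise condition); all other
experiments run at the default, field-realistic noise.

## Known limitations

* The engine is CPU/NumPy; it is sized for 16-unit networks and 89-step
  sequences, not for large-scale training.
* MAE's subgradient at zero is taken as 0; with float64 this is
  essentially never hit in practice.
* Binary PLY support covers little-endian float32 vertex data with
  exactly the seven expected properties; anything else is rejected with a
  format error rather than coerced.
* Attention profiles are descriptive, not causal: they report where the
  trained extractor put its weights, and are themselves averaged over
  channels and examples.
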