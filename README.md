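# canopynet

Multitask deep learning for **simultaneous prediction of wheat grain yield
and grain protein content (GPC)** from near-daily time-series canopy
traits, as collected by proximal-sensing phenotyping platforms (fused
LiDAR + four-band multispectral point clouds).

Yield and GPC are the two optimization targets of wheat breeding and
cultivation, and they trade off against each other. Instead of fitting one
model per target, `canopynet` fuses a structural trait (e.g. mean canopy
height, Hmean) and a spectral trait (e.g. GNDVI) at the feature level and
predicts both targets from one network with a weighted multitask loss

```
L = λ_GPC · MAE_GPC + λ_yield · MAE_yield ,   λ_GPC + λ_yield = 1 .
```

The package provides, as a tested library plus CLI:

* **trait extraction** — GNDVI, CVI, NCPI, MCARI and Hmean, H99, PLA,
  Volume from fused per-plot point clouds (PLY or CSV);
* **dataset preparation** — 89-day vectorization (DAS 107–195), linear
  interpolation of missing days, jitter/scale/resample augmentation with
  target perturbation, min–max normalization, 80/10/10 splits;
* **a model zoo** — one/two-input × one/two-output network topologies with
  five interchangeable time-series extractors (FC, RNN, LSTM, 1-D CNN,
  temporal attention), trained with Adam + early stopping on a small
  NumPy autodiff engine included in the package;
* **evaluation** — R², RMSE, rRMSE on the denormalized scale and a
  multi-seed model-comparison matrix;
* **attention analysis** — per-day importance profiles (%/day over the 89
  sensing days) and pre/post-anthesis stage summaries;
* **a synthetic trial generator** — a 480-plot split-plot experiment
  (120 varieties × 2 nitrogen levels × 2 replications) with realistic
  trait dynamics, a nitrogen effect and a planted yield–GPC trade-off, so
  the whole pipeline is testable without any external dataset.

See `docs/methods.md` for the model and generator details.

## Worked example

```python
from canopynet.synthetic import simulate_dataset
from canopynet.prep import prepare_dataset, PrepConfig
from canopynet.models import ModelSpec
from canopynet.training import TrainConfig, train
from canopynet.evaluation import evaluate
from canopynet.attention import extract_attention_profile, stage_importance

plots, series = simulate_dataset(seed=1)                   # 480-plot trial
ds = prepare_dataset(plots, series, PrepConfig(), seed=1)  # 1000 examples
spec = ModelSpec("two_to_two", "ATTENTION", ("GNDVI", "Hmean"))
trained = train(spec, ds, TrainConfig(max_epochs=300,
                                      early_stop_patience=25, seed=0))
report = evaluate(trained, ds)
for target, m in report.metrics.items():
    print(f"{target}: R2={m['r2']:.3f}  RMSE={m['rmse']:.1f}  "
          f"rRMSE={m['rrmse']:.2f}%")
for profile in extract_attention_profile(trained, ds):
    pre, post = stage_importance(profile, anthesis_das=160)
    print(f"{profile.input_trait} attention: pre {pre:.2f} %/day, "
          f"post {post:.2f} %/day")
```

prints (about a minute on one CPU):

```
yield: R2=0.807  RMSE=404.3  rRMSE=7.47%
gpc: R2=0.731  RMSE=0.4  rRMSE=3.38%
GNDVI attention: pre 0.90 %/day, post 1.46 %/day
Hmean attention: pre 0.82 %/day, post 1.57 %/day
```

i.e. the fused attention model recovers both planted targets on held-out
plots (yield to within ~404 kg/ha, GPC to within ~0.4 points), and both
traits' daily importance concentrates after anthesis — the grain-filling
period carries most of the predictive signal.

The same pipeline is scriptable from the shell:

```bash
canopynet simulate  --seed 1 --out-dir run/
canopynet prepare   --plots run/plots.csv --traits run/traits.csv --out-dir run/
canopynet train     --dataset run/prepared.npz --out-dir run/
canopynet evaluate  --dataset run/prepared.npz --model run/model.npz --out-dir run/
canopynet attention --dataset run/prepared.npz --model run/model.npz --out-dir run/
canopynet reproduce-study --seed 1 --out-dir study/   # full comparison matrix
```

Every subcommand accepts a YAML `--config` (generator sizes, prep,
model, training and study sections) and writes a JSON run manifest.

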