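# wearsleep

Sleep-stage prediction from consumer wearable time series: heart rate,
step/activity counts and a light-entrained circadian oscillator, fed to
memoryless classifiers and a from-equations LSTM over sliding-window
context, with weighted multiclass evaluation.

## Who this is for

Researchers studying whether wrist-wearable signals (actigraphy + PPG heart
rate) carry enough information to recover the four-class hypnogram — wake,
light (N1+N2), deep (N3) and REM — that polysomnography would score, and
how much *temporal context* (how far back a model looks) contributes to
that recovery.  Real device collections are private or access-restricted,
so the package ships a calibrated synthetic-night generator: every stage of
the pipeline is testable end to end with no data download, and the same
code paths accept real epoch tables supplied as delimited text.

## What is inside

| module | role |
| --- | --- |
| `wearsleep.synthetic` | labelled multimodal nights: semi-Markov cycle hypnograms, stage-conditional HR/step/acceleration emission, device-style Short/Long duplicate interval records |
| `wearsleep.records` | interval-record expansion, short-wins conflict merging, floor alignment, natural joins, null-row removal, named instance schemas |
| `wearsleep.features` | cosine clock, van der Pol circadian drive with Process L light transduction, activity counts from raw acceleration, Gaussian/DoG filtering, HR variation, log-positify and min-max scaling |
| `wearsleep.windowing` | sliding-window sequences: each epoch with its `ns` predecessors, never crossing gaps or night boundaries |
| `wearsleep.models`, `wearsleep.lstm` | LR/RF/kNN/SVM/MLP suite (scikit-learn, weighted-F1 grid selection) and a NumPy LSTM built from the gate equations with BPTT + Adam; memory-step sweep |
| `wearsleep.evaluation` | weighted precision/recall/F1, Cohen's κ, multiclass Matthews coefficient, confusion matrices, sweep summaries, hypnogram comparison plots |

The circadian drive integrates

```
dx/dt  = (π/12)(x_c + B)
dx_c/dt = (π/12)[ μ(x_c − 4x_c³/3) − x(24/(0.99669 τ_x))² + kB ]
```

with μ = 0.23 and τ_x = 24.2 h (free-running period 0.99669 τ_x), where B
is the Process-L light drive inferred from activity.  The LSTM implements
the classic gates f, i, o with logistic activations, a tanh candidate
state, `c_t = i⊙c̄ + f⊙c_{t−1}`, `h_t = o⊙tanh(c_t)`, a dense softmax
readout and categorical cross-entropy loss.

## Worked example

```python
import pandas as pd
import wearsleep as ws

cfg = ws.GeneratorConfig(seed=7, epoch_interval=60)
nights = ws.generate_nights(cfg, 6, seed=7)
pool = ws.EpochTable(
    pd.concat(ws.night_feature_table(n).frame for n in nights), 60
)
print(ws.imbalance_report(pool.frame["stage"]).round(3).to_dict())

from wearsleep.models import evaluate_at_ns
cfg_lstm = ws.TrainConfig(hidden_size=8, epochs=15, learning_rate=0.02, seed=0)
for ns in (0, 4):
    rep = evaluate_at_ns(pool, ns, cfg_lstm)
    print(f"LSTM ns={ns}: ACC {rep.accuracy:.3f}  kappa {rep.cohen_kappa:.3f}")
```

prints

```
{'REM': 0.194, 'deep': 0.182, 'light': 0.5, 'wake': 0.124}
LSTM ns=0: ACC 0.731  kappa 0.575
LSTM ns=4: ACC 0.899  kappa 0.844
```

The pooled stage mix shows the natural imbalance of sleep (half the night
is light sleep), and accuracy rises when the model is given four minutes of
history — stage dwell times make the recent past informative about the
present.

The same pipeline is scriptable from a shell:

```sh
wearsleep simulate --nights 2 --seed 5 --out nights/
wearsleep prepare --records nights/night000_records.csv \
                  --signals nights/night000_signals.csv --out inst.csv
wearsleep sweep --instance inst.csv --ns 1:8 --out sweep.json
```

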