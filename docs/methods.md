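# Methods

## The problem

Consumer wrist wearables report heart rate (PPG), movement (accelerometer
step/activity counts) and summarized sleep-stage interval records.  The
question this package operationalizes is whether those channels, plus a
model of the circadian drive, suffice to recover the four-class hypnogram
(wake / light / deep / REM at a fixed epoch interval of 15–60 s), and how
much predictive value lies in *temporal context* — the epochs immediately
preceding the one being classified.

Because realistic device collections are private or access-restricted, the
package is built around a synthetic-night generator whose statistical
structure matches what sleep medicine reports for healthy adults.  All
empirical claims in the test suite are claims about this generator, not
about any real cohort (see "What the generator does and does not emulate").

## Synthetic night model

A night (default 480 min at 30 s epochs) is composed of 4–6 NREM/REM
cycles averaging roughly 90 min.  Per night, a stage-duration budget is
drawn around the target mix — wake 12.2 %, light 50.1 %, deep 18.1 %,
REM 19.6 % — with 4 % multiplicative jitter, renormalized to the night
length, then partitioned across cycles under dwell-time bounds:

* N1 1–5 min, N2 10–60 min, N3 20–40 min, REM 10–60 min per maximal run;
* deep sleep only in the first *k* cycles (k chosen so each bout fits its
  bounds), largest bouts earliest;
* REM bouts lengthen across the night (weights 0.55→1.45);
* light sleep is skewed toward later cycles, compensating the waning deep
  share — together with the small first REM bout this keeps the first
  cycle the shortest in most nights;
* wake is a longer sleep-onset bout plus brief awakenings before each
  cycle.

Partitioning uses proportional splitting with box constraints and
largest-remainder rounding to whole epochs, so the per-night budget is
conserved exactly.  Pooled over many nights the epoch fractions converge
to the targets by construction — no transition-matrix tuning is involved.
With 50 nights the pooled fractions sit within a few tenths of a
percentage point of the targets for any seed.

**Memoryless null.** With `history_dependence=False` the generator instead
draws each epoch's stage from the chain P = (1−γ)I + γ·1πᵀ whose
stationary law is exactly the target mix.  The default γ = 1 makes epochs
independent: past stages then carry no information about the present, the
clean null for the memory-effect experiments.  Any γ < 1 gives a
persistent first-order chain — note that persistence alone already makes
history informative (a model can denoise heart rate by averaging within a
dwell), so a persistent chain is *not* a valid negative control even
though its transition hazard is dwell-independent.

**Emission model.** Heart rate is stage-conditionally Gaussian with the
physiological ordering wake > REM > light > deep; defaults are
wake 72±5, REM 66±4, light 60±4, deep 54±3.5 bpm — stage separations of
~6 bpm with within-stage SDs of 3.5–5 bpm, in line with overnight cardiac
variation in healthy adults.  Steps occur only in wake epochs (Bernoulli
rate 0.3, burst size 1–39).  Triaxial acceleration, generated on request,
is white noise in g with a gravity offset on z, inflated ×5 during wake
and ×1.5 during REM.  These are emissions for pipeline testing, not
waveform-level physiology.

**Interval records.** The hypnogram is run-length encoded into Long
records; at a configurable duplicate rate, epochs are corrupted in the
Long stream and covered by overlapping Short records (native or
double-length interval) carrying the true stage.  Short-wins merging after
expansion therefore recovers the hypnogram exactly at any rate — the
round-trip identity the preprocessing tests rely on.

## Preprocessing

Records expand to `duration/interval` entries; durations that are not a
multiple of the target interval are truncated to the last full epoch (a
pad policy is available) and logged.  Merging resolves Short/Long
conflicts slot-wise after expansion — the only order in which a 60 s Short
record overlapping two 30 s slots is resolvable.  Auxiliary streams are
floor-aligned to the epoch grid (earliest record wins within a cell, on
the assumption the state does not change inside one epoch); all tables are
then inner-joined on time, null rows dropped, and a named instance schema
column-selects the result.  Timestamps are timezone-naive local instants;
epochs are half-open `[t, t+interval)`.

The shipped instance schemas mirror a seven-instance layout (five
activity/HR/HRV/temperature/SpO2 instances at 60 s plus two
actigraphy-style instances at 30 s and 15 s).  One published feature count
(19 for the HRV instance) is inconsistent with its four listed HRV
channels; the schema here drops the `coverage` channel to keep the printed
count.  The 15 s interval of the largest instance is likewise reported
inconsistently elsewhere as 30 s; it is configurable, defaulting to 15 s.

## Features

* **Cosine clock** C = cos(2πt/24), t in hours — the printed form cos(t)
  is dimensionally ambiguous; a 24 h period makes the clock "rise and fall
  overnight" as intended.
* **Circadian drive**: the two-variable van der Pol-type oscillator with
  μ = 0.23, τ_x = 24.2 h, integrated with classical fixed-step RK4
  (dt = 60 s default, capped at 60 s; a halved-step rerun agrees to
  <1e-6/day).  The origin is an exact fixed point in darkness, and the
  free-running period measured by zero crossings matches 0.99669·τ_x
  within 0.4 % across τ_x ∈ {23.5, 24.2, 24.6}.  The light term enters as
  an additive k·B in the x_c equation (k = 0.55), following the printed
  form of the model this implements; the cited Kronauer-family variant
  multiplies x by ((24/0.99669τ_x)² + kB) instead — identical when B ≡ 0,
  which is all the oracle tests use.  B comes from Process L
  (α(I) = α₀(I/I₀)^p, dn/dt = 60[α(1−n) − βn],
  B = G·α·(1−n)(1−0.4x)(1−0.4x_c)) with α₀ = 0.05 min⁻¹, β = 0.0075 min⁻¹,
  I₀ = 9500 lux, p = 0.5, G = 33.75 — all configurable.
* **Activity → light**: counts above a threshold (default 0) map to
  1000 lux, else 0 — movement implies lights on; wearables measure no
  illuminance.
* **Acceleration → counts**: 0.25 Hz high-pass per axis, magnitude,
  per-epoch maximum, ×1000 to integer counts.  The published constants of
  the original count technique are not reprinted anywhere accessible, so
  the coefficients are declared defaults.
* **Cardiac channels**: HR interpolated to 1 s and Gaussian-smoothed
  (σ = 120 s — the recipe names no separate smoothing width, so the DoG's
  narrow band is reused); a σ = 120 s vs 600 s difference-of-Gaussians
  band-pass; HR variation |Δhr|/mean.  The σ = 50 activity smoothing
  carries no printed unit and is interpreted as 50 samples; `FilterSpec`
  can express either convention.
* **Scaling**: columnwise min-max with train-fitted bounds (no clipping;
  constant columns map to 0) and the order-preserving positive rescale
  y ↦ log2(y + 1 − min y).

The default per-night modelling table is (time, cosine, circadian, hr,
hr_var, steps) plus the stage label: deliberately *per-epoch* (unsmoothed
HR), so that the memory experiments measure the value of history rather
than of a non-causal smoother baked into the features.

## Windowing and models

Each training example is the feature rows of epochs i−ns…i with the stage
of epoch i; windows never cross a timestamp gap or night boundary (mixing
subjects inside one window would leak across them), and stride is 1.  A
contiguous N-row segment yields N − ns sequences, so the windowed label
distribution equals the source distribution over indices ≥ ns.

Memoryless models consume flattened windows and are scikit-learn
estimators behind one interface, selected by 3-fold cross-validated
weighted F1 over small grids (grid × folds stays in the tens-to-hundreds
of fits).  Splits are stratified random 0.75/0.25 by default — the
alternative subject-held-out split exists because "subject-independent
stratified" is self-contradictory for windowed data; stratified random is
the default, subject-held-out the leakage study.

The LSTM is implemented in NumPy (float64) from the gate equations, with a
tanh candidate state by default; a logistic-candidate variant is a config
switch, since the printed equations use the logistic symbol for the
candidate while the surrounding text says tanh.  Training is full BPTT
with Adam (canonical rates, lr 1e-3 default, batch 128, hidden 16,
epochs 50; batch size and hidden size are declared defaults, not inferred
from any source).  Gradients are validated against central finite
differences (<1e-4 relative) — the module's core correctness oracle — and
training is seed-deterministic end to end.  Divergence (loss >10×
initial) aborts with diagnostics.

## Evaluation

Weighted precision/recall/F1 (support weights), Cohen's κ from marginal
chance agreement, Matthews coefficient in its multiclass covariance form
(the natural reading of an otherwise undefined "MC" column), RMSE on
one-hot residuals when probabilities are available, and a predicted×true
confusion matrix.  Support-weighted recall is identically accuracy — the
identity is asserted on random fixtures and explains why ACC and Recall
columns coincide in this literature.  All reported rates are on the [0,1]
scale uniformly; published tables in this area sometimes mix [0,1] and
percentage scales within one column.

Sweep summaries report the first ns attaining the maximum accuracy (ties
to the smallest ns, logged) plus top-3 boxplot data.

## Scaled-down experiment sizes

The memory-effect experiments in the test suite use 5 seeds × 20 nights at
60 s epochs (~9,600 epochs per seed), LSTM hidden 8, 15 epochs, lr 0.02,
history depths ns ∈ {0, 4, 8} — sizes chosen so the full experiment is a
routine desk run.  On the history-dependent generator the random forest
exceeds the majority-class rate by well over 0.15 and median LSTM accuracy
at ns ∈ {4, 8} exceeds ns = 0 by ~0.15; on the iid null the three depths
agree within one standard deviation.

## What passing tests do and do not show

The generator reproduces stage *composition*, cycle architecture, dwell
bounds, stage-conditional HR ordering and the duplicate-record mechanics.
It does not emulate PPG/ECG waveforms, HRV spectra, inter-subject
variability, device dropout, arousal microstructure, or daytime activity.
Model accuracies on synthetic nights therefore demonstrate that the
pipeline can extract the structure the generator encodes — they are not
estimates of real-data performance, which depends on sensor noise and
physiology the emission model deliberately simplifies.

## Numerical and degenerate-input choices

RK4 state non-finiteness raises with the step index; Process-L activation
is clipped to [0,1] after each step.  Gaussian kernels are unit-sum, DoG
kernels zero-sum, truncated at ±4·max σ, reflect padding by default;
series shorter than the kernel are an error.  Cross-entropy clips
probabilities at 1e-12 and logs clip events.  Single-sample HR series
extend as constants with a warning.  Zero-variance emissions, empty
metric inputs, conflicting Short records, column collisions in joins and
missing schema features all raise explicit errors.
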