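"""Synthetic multimodal wearable nights.

The downstream pipeline (record expansion, feature engineering, windowed
sequence models) is exercised against generated nights that carry the
statistical structure sleep medicine describes for healthy adults:

* a night is 4–6 NREM/REM cycles of roughly 90 minutes, the first cycle
  the shortest;
* stage bouts have characteristic dwell times — N1 1–5 min, N2 10–60 min,
  N3 (deep) 20–40 min, REM 10–60 min — with deep sleep concentrated in the
  early cycles and REM lengthening across the night;
* pooled over many nights the four-class stage mix is strongly imbalanced
  (≈12% wake, 50% light, 18% deep, 20% REM);
* heart rate is stage-conditional (wake > REM > light > deep), steps occur
  only during wake bouts, and the device emits overlapping Short/Long
  interval records whose short-wins merge recovers the true hypnogram.

Because the stage budget of every night is drawn around the target
proportions and then partitioned under the dwell-time bounds, the pooled
epoch fractions converge to the targets by construction rather than by
tuning a transition matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import LONG, SHORT, EpochTable, SleepRecord
from .stages import FOUR_CLASS, N1, N2, N3, REM, WAKE, StageLabelSet

logger = logging.getLogger(__name__)

DEFAULT_START = pd.Timestamp("2021-12-16 22:00:00")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic night.

    Durations are minutes unless noted.  ``dwell_ranges`` bound each
    maximal stage run; ``target_proportions`` set the long-run four-class
    epoch mix.  With ``history_dependence`` (default) the night is built
    from dwell-constrained cycles, so elapsed time in a stage carries
    information about the next transition; switched off, stages follow a
    memoryless per-epoch Markov chain with the same stationary mix.
    """

    seed: int = 0
    night_length: int = 480  # minutes
    epoch_interval: int = 30  # seconds
    n_cycles_range: tuple[int, int] = (4, 6)
    cycle_length_mean: float = 90.0
    dwell_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            N1: (1, 5),
            N2: (10, 60),
            N3: (20, 40),
            REM: (10, 60),
        }
    )
    target_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "wake": 0.122,
            "light": 0.501,
            "deep": 0.181,
            "REM": 0.196,
        }
    )
    hr_emission: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wake": (72.0, 5.0),
            "REM": (66.0, 4.0),
            "light": (60.0, 4.0),
            "deep": (54.0, 3.5),
        }
    )
    step_emission: dict[str, float] = field(
        default_factory=lambda: {"wake": 0.3, "light": 0.0, "deep": 0.0, "REM": 0.0}
    )
    accel_noise_sd: float = 0.02  # g
    accel_fs: float = 10.0  # Hz
    include_acceleration: bool = False
    history_dependence: bool = True
    #: null model only: per-epoch probability of re-drawing the stage from
    #: the target mix.  1.0 makes epochs independent (the pure no-memory
    #: null); lower values give a persistent first-order Markov chain.
    memoryless_switch_rate: float = 1.0
    duplicate_rate: float = 0.1
    start: pd.Timestamp = DEFAULT_START

    def __post_init__(self) -> None:
        if self.epoch_interval not in (15, 30, 60):
            raise ValueError("epoch_interval must be one of 15, 30, 60 s")
        for s, (lo, hi) in self.dwell_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid dwell range for {s}: ({lo}, {hi})")
        total = sum(self.target_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target_proportions sum to {total}, not 1")

    @property
    def epochs_per_minute(self) -> int:
        return 60 // self.epoch_interval

    @property
    def n_epochs(self) -> int:
        return self.night_length * self.epochs_per_minute


@dataclass
class SyntheticNight:
    """One generated night: ground truth plus everything the device emits."""

    hypnogram: EpochTable
    heart_rate: EpochTable
    steps: EpochTable
    sleep_records: list[SleepRecord]
    acceleration: pd.DataFrame | None = None  # columns ax, ay, az in g
    config: GeneratorConfig | None = None


# ---------------------------------------------------------------------------
# bounded partitioning
# ---------------------------------------------------------------------------

def _split_bounded(
    total: float,
    weights: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Split ``total`` proportionally to ``weights`` subject to box bounds.

    Clamped parts stay clamped; the residual is redistributed among the
    free parts until convergence.  Raises if total lies outside
    [sum(lo), sum(hi)].
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    w = np.asarray(weights, float)
    if total < lo.sum() - 1e-9 or total > hi.sum() + 1e-9:
        raise ValueError(
            f"cannot split {total:.2f} into parts bounded by "
            f"[{lo.sum():.2f}, {hi.sum():.2f}]"
        )
    x = total * w / w.sum()
    for _ in range(50):
        x = np.clip(x, lo, hi)
        resid = total - x.sum()
        if abs(resid) < 1e-9:
            break
        free = (x < hi - 1e-12) if resid > 0 else (x > lo + 1e-12)
        if not free.any():
            break
        x[free] += resid * w[free] / w[free].sum()
    return np.clip(x, lo, hi)


def _round_to_epochs(durations_min: np.ndarray, epochs_per_minute: int, total_epochs: int) -> np.ndarray:
    """Largest-remainder rounding of minute durations to whole epochs."""
    raw = np.asarray(durations_min, float) * epochs_per_minute
    base = np.floor(raw).astype(int)
    short = total_epochs - base.sum()
    if short < 0:
        # over-allocation can only come from float slack; trim largest parts
        order = np.argsort(raw - base)
        for i in order[: -short]:
            base[i] -= 1
    elif short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# hypnogram generation
# ---------------------------------------------------------------------------

def _night_segments(config: GeneratorConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    """Plan one night as an ordered list of (fine stage, minutes)."""
    dw = config.dwell_ranges
    n_lo, n_hi = config.n_cycles_range
    min_needed = n_lo * (dw[N1][0] + dw[N2][0] + dw[REM][0] + 1.0) + dw[N3][0]
    if config.night_length < min_needed:
        raise ValueError(
            f"night_length {config.night_length} min too short for "
            f"{n_lo} cycles (needs ≥ {min_needed:.0f} min)"
        )
    night = float(config.night_length)
    epoch_min = 1.0 / config.epochs_per_minute
    lo_l = dw[N1][0] + dw[N2][0] + 1.0
    # a cycle needs at least a wake epoch, minimal light and minimal REM
    min_cycle = epoch_min + lo_l + dw[REM][0] + 0.5
    n_hi_eff = min(n_hi, int((night - dw[N3][0] - 0.5) // min_cycle))
    if n_hi_eff < n_lo:
        raise ValueError(
            f"night_length {config.night_length} min too short for "
            f"{n_lo} cycles of ≥ {min_cycle:.0f} min plus a deep bout"
        )
    n_c = int(rng.integers(n_lo, n_hi_eff + 1))

    # stage budgets for the night, jittered around the targets
    p = config.target_proportions
    budgets = np.array([p["wake"], p["light"], p["deep"], p["REM"]]) * night
    budgets *= rng.normal(1.0, 0.04, size=4)
    budgets *= night / budgets.sum()
    b_wake, b_light, b_deep, b_rem = budgets

    # number of deep cycles and feasible per-stage budget windows
    lo_d, hi_d = dw[N3]
    lo_r, hi_r = dw[REM]
    k_lo = max(1, int(np.ceil(b_deep / (hi_d - 0.5))))
    k_hi = max(k_lo, min(n_c, int(b_deep // (lo_d + 0.5))))
    k = int(np.clip(round(b_deep / ((lo_d + hi_d) / 2)), k_lo, k_hi))
    lims = {
        "wake": (n_c * epoch_min, n_c * 30.0),
        "deep": (k * (lo_d + 0.5), k * (hi_d - 0.5)),
        "rem": (n_c * (lo_r + 0.5), n_c * (hi_r - 0.5)),
    }
    b = {
        "wake": float(np.clip(b_wake, *lims["wake"])),
        "deep": float(np.clip(b_deep, *lims["deep"])),
        "rem": float(np.clip(b_rem, *lims["rem"])),
    }
    # light absorbs the remainder; if the clips above squeezed it outside
    # its own feasible window, hand the difference back (REM, then wake,
    # then deep) so every stage stays inside its dwell-implied bounds
    hi_l_per = np.r_[
        np.full(k, dw[N1][1] + 2 * dw[N2][1] - 1.0),
        np.full(n_c - k, dw[N1][0] + dw[N2][1] - 0.5),
    ]
    lo_light, hi_light = n_c * lo_l, float(hi_l_per.sum())
    for _ in range(2):
        b_light = night - sum(b.values())
        if b_light < lo_light:
            need = lo_light - b_light
            for s in ("rem", "wake", "deep"):
                give = min(need, b[s] - lims[s][0])
                b[s] -= give
                need -= give
            if need > 1e-9:
                raise ValueError(
                    f"night_length {config.night_length} min too short for "
                    f"{n_c} cycles under the configured dwell ranges"
                )
        elif b_light > hi_light:
            excess = b_light - hi_light
            for s in ("rem", "wake", "deep"):
                take = min(excess, lims[s][1] - b[s])
                b[s] += take
                excess -= take
            if excess > 1e-9:
                raise ValueError("night_length too long for the dwell ranges")
    b_light = night - sum(b.values())

    # deep sleep concentrated in the first k cycles, one bout each
    deep = np.zeros(n_c)
    deep[:k] = _split_bounded(
        b["deep"], rng.uniform(0.9, 1.1, k) * np.linspace(1.1, 0.9, k),
        np.full(k, lo_d + 0.5), np.full(k, hi_d - 0.5),
    )

    # REM lengthens across the night
    rem = _split_bounded(
        b["rem"], rng.uniform(0.9, 1.1, n_c) * np.linspace(0.55, 1.45, n_c),
        np.full(n_c, lo_r + 0.5), np.full(n_c, hi_r - 0.5),
    )

    # wake: a sleep-onset bout plus brief awakenings before each cycle
    w_weights = np.r_[1.5, rng.uniform(0.8, 1.2, n_c - 1)]
    wake = _split_bounded(
        b["wake"], w_weights, np.full(n_c, epoch_min), np.full(n_c, 30.0)
    )

    # light skewed toward the later cycles: together with the small first
    # REM bout this keeps the first cycle the shortest
    light = _split_bounded(
        b_light, rng.uniform(0.95, 1.05, n_c) * np.linspace(0.55, 1.45, n_c),
        np.full(n_c, lo_l), hi_l_per,
    )

    segments: list[tuple[str, float]] = []
    for c in range(n_c):
        segments.append((WAKE, wake[c]))
        n1 = float(
            np.clip(
                rng.uniform(*dw[N1]),
                max(dw[N1][0], light[c] - dw[N2][1] + 0.5),
                min(dw[N1][1], light[c] - dw[N2][0] - 0.5),
            )
        )
        n2_total = light[c] - n1
        if deep[c] > 0 and n2_total > dw[N2][1] - 0.25:
            # split the light budget around the deep bout
            parts = _split_bounded(
                n2_total, rng.uniform(0.9, 1.1, 2),
                np.full(2, dw[N2][0] + 0.25), np.full(2, dw[N2][1] - 0.25),
            )
            segments += [(N1, n1), (N2, parts[0]), (N3, deep[c]), (N2, parts[1])]
        elif deep[c] > 0:
            segments += [(N1, n1), (N2, n2_total), (N3, deep[c])]
        else:
            segments += [(N1, n1), (N2, n2_total)]
        segments.append((REM, rem[c]))
    return segments


def generate_hypnogram(
    config: GeneratorConfig, label_set: StageLabelSet = FOUR_CLASS
) -> EpochTable:
    """Generate one night's stage sequence on the epoch grid.

    Deterministic given ``config.seed``.  Labels are drawn from
    ``label_set`` (fine AASM stages are coarsened through its mapping).
    """
    rng = np.random.default_rng([config.seed, 0])
    if config.history_dependence:
        segments = _night_segments(config, rng)
        durations = np.array([d for _, d in segments])
        epochs = _round_to_epochs(durations, config.epochs_per_minute, config.n_epochs)
        labels: list[str] = []
        for (stage, _), n in zip(segments, epochs):
            labels.extend([label_set.coarsen(stage)] * int(n))
    else:
        labels = _markov_hypnogram(config, label_set, rng)
    index = pd.date_range(
        config.start, periods=config.n_epochs, freq=pd.Timedelta(seconds=config.epoch_interval)
    )
    frame = pd.DataFrame({"stage": labels}, index=index)
    frame.index.name = "timestamp"
    return EpochTable(frame, config.epoch_interval)


def _markov_hypnogram(
    config: GeneratorConfig, label_set: StageLabelSet, rng: np.random.Generator
) -> list[str]:
    """Memoryless null model: P = (1-γ)I + γ·1πᵀ, stationary mix exactly π.

    At the default γ = 1 every epoch is an independent draw from π, so past
    epochs carry no information about the current stage — the negative
    control for the memory-effect experiments.
    """
    coarse = list(config.target_proportions)
    pi = np.array([config.target_proportions[s] for s in coarse])
    gamma = config.memoryless_switch_rate
    state = int(rng.choice(len(coarse), p=pi))
    out = []
    jumps = rng.random(config.n_epochs) < gamma
    targets = rng.choice(len(coarse), size=config.n_epochs, p=pi)
    for k in range(config.n_epochs):
        if jumps[k]:
            state = int(targets[k])
        out.append(coarse[state])
    return out


def count_cycles(hypnogram: EpochTable) -> int:
    """Number of NREM/REM cycles = number of maximal REM runs."""
    stages = hypnogram.frame["stage"].to_numpy()
    is_rem = stages == "REM"
    return int(np.sum(is_rem[1:] & ~is_rem[:-1]) + (1 if is_rem[0] else 0))


# ---------------------------------------------------------------------------
# sensor emission
# ---------------------------------------------------------------------------

def generate_signals(hypnogram: EpochTable, config: GeneratorConfig) -> SyntheticNight:
    """Emit per-epoch heart rate, steps (and optional acceleration).

    HR is stage-conditionally Gaussian with the physiological ordering
    wake > REM > light > deep; steps are sparse bursts confined to wake
    epochs; acceleration (when enabled) is stage-modulated noise at
    ``config.accel_fs``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    stages = hypnogram.frame["stage"].to_numpy()
    unknown = set(stages) - set(config.hr_emission)
    if unknown:
        raise ValueError(f"no emission model for stages {sorted(unknown)}")

    means = np.array([config.hr_emission[s][0] for s in stages])
    sds = np.array([config.hr_emission[s][1] for s in stages])
    hr = rng.normal(means, sds)

    rates = np.array([config.step_emission.get(s, 0.0) for s in stages])
    bursts = rng.random(len(stages)) < rates
    steps = np.where(bursts, rng.integers(1, 40, size=len(stages)), 0)

    idx = hypnogram.timestamps
    hr_table = EpochTable(pd.DataFrame({"hr": hr}, index=idx), hypnogram.interval)
    steps_table = EpochTable(pd.DataFrame({"steps": steps}, index=idx), hypnogram.interval)

    accel = None
    if config.include_acceleration:
        n_per_epoch = int(config.accel_fs * config.epoch_interval)
        factor = np.where(stages == "wake", 5.0, np.where(stages == "REM", 1.5, 1.0))
        sd = np.repeat(config.accel_noise_sd * factor, n_per_epoch)
        t = idx[0] + pd.to_timedelta(
            np.arange(len(stages) * n_per_epoch) / config.accel_fs, unit="s"
        )
        accel = pd.DataFrame(
            {
                "ax": rng.normal(0, sd),
                "ay": rng.normal(0, sd),
                "az": 1.0 + rng.normal(0, sd),  # gravity on z
            },
            index=t,
        )

    records = emit_sleep_records(hypnogram, config.duplicate_rate, int(config.seed))
    return SyntheticNight(
        hypnogram=hypnogram,
        heart_rate=hr_table,
        steps=steps_table,
        sleep_records=records,
        acceleration=accel,
        config=config,
    )


# ---------------------------------------------------------------------------
# interval-record emission
# ---------------------------------------------------------------------------

def emit_sleep_records(
    hypnogram: EpochTable, duplicate_rate: float, seed: int
) -> list[SleepRecord]:
    """Run-length encode a hypnogram into device-style interval records.

    With ``duplicate_rate`` > 0, a fraction of epochs is "corrupted" in the
    Long stream (carrying a wrong stage) and covered by overlapping Short
    records that carry the true stage — the pattern real devices produce
    around stage transitions.  Expanding and short-wins merging the emitted
    records therefore recovers the hypnogram exactly at any rate.
    """
    if not 0.0 <= duplicate_rate <= 1.0:
        raise ValueError(f"duplicate_rate must be in [0, 1], got {duplicate_rate}")
    rng = np.random.default_rng([seed, 2])
    stages = hypnogram.frame["stage"].to_numpy().copy()
    idx = hypnogram.timestamps
    interval = hypnogram.interval
    labels = list(dict.fromkeys(stages))  # stage vocabulary, stable order

    records: list[SleepRecord] = []
    corrupted = stages.copy()
    if duplicate_rate > 0:
        hit = rng.random(len(stages)) < duplicate_rate
        for k in np.flatnonzero(hit):
            others = [s for s in labels if s != stages[k]] or [stages[k]]
            corrupted[k] = others[int(rng.integers(len(others)))]
        # Short records carry the truth; adjacent hits with one true stage
        # coalesce into a double-length short record (Table-style 60s-over-30s)
        k = 0
        hits = np.flatnonzero(hit)
        hitset = set(hits.tolist())
        while k < len(hits):
            j = hits[k]
            if (
                k + 1 < len(hits)
                and hits[k + 1] == j + 1
                and stages[j] == stages[j + 1]
            ):
                records.append(
                    SleepRecord(idx[j], 2 * interval, stages[j], SHORT, interval)
                )
                k += 2
            else:
                records.append(SleepRecord(idx[j], interval, stages[j], SHORT, interval))
                k += 1

    # long records: RLE of the (possibly corrupted) long stream
    change = np.flatnonzero(corrupted[1:] != corrupted[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(corrupted)]
    for a, b in zip(starts, ends):
        records.append(
            SleepRecord(idx[a], (b - a) * interval, corrupted[a], LONG, interval)
        )
    records.sort(key=lambda r: (r.start, r.cycle_type))
    return records


def table1_records() -> list[SleepRecord]:
    """The six-row mixed Short/Long duplicate fixture (already expanded rows,
    so each record's duration equals its interval)."""
    T = pd.Timestamp
    return [
        SleepRecord(T("2021-12-16 06:37:00"), 30, "light", LONG, 30),
        SleepRecord(T("2021-12-16 06:37:30"), 30, "light", LONG, 30),
        SleepRecord(T("2021-12-16 06:38:00"), 60, "wake", SHORT, 30),
        SleepRecord(T("2021-12-16 06:38:00"), 30, "light", LONG, 30),
        SleepRecord(T("2021-12-16 06:38:30"), 30, "light", LONG, 30),
        SleepRecord(T("2021-12-16 06:38:30"), 30, "wake", SHORT, 30),
    ]


# ---------------------------------------------------------------------------
# multi-night convenience
# ---------------------------------------------------------------------------

def generate_nights(
    config: GeneratorConfig,
    n_nights: int,
    seed: int | None = None,
    *,
    with_signals: bool = True,
    label_set: StageLabelSet = FOUR_CLASS,
) -> list[SyntheticNight] | list[EpochTable]:
    """Generate ``n_nights`` independent nights, one day apart.

    ``seed`` (default ``config.seed``) drives a child seed per night, so a
    pool is reproducible regardless of how many nights are drawn before it.
    With ``with_signals=False`` only hypnograms are returned.
    """
    base_seed = config.seed if seed is None else seed
    child = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_nights)
    out = []
    for i in range(n_nights):
        cfg = replace(
            config, seed=int(child[i]), start=config.start + pd.Timedelta(days=i)
        )
        hyp = generate_hypnogram(cfg, label_set)
        out.append(generate_signals(hyp, cfg) if with_signals else hyp)
    return out
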