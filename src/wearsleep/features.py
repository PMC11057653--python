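"""Engineered channels: clock, circadian drive, activity and cardiac features.

The circadian drive is the light-entrained van der Pol-type oscillator

    dx/dt  = (π/12) (x_c + B)
    dx_c/dt = (π/12) [ μ (x_c − 4x_c³/3) − x (24/(0.99669 τ_x))² + k·B ]

with μ = 0.23 and free-running period 0.99669·τ_x hours.  B is the light
drive produced by Process L, the photoreceptor activation model
α(I) = α₀ (I/I₀)^p, dn/dt = 60 [α(I)(1−n) − β n],
B = G α(I) (1−n) (1−0.4x)(1−0.4x_c).  Wearables do not measure light, so
illuminance is inferred from activity (movement implies lights on).

Cardiac channels follow the wearable-actigraphy feature recipe: heart rate
interpolated to 1 s and Gaussian-smoothed, a difference-of-Gaussians
(σ = 120 s vs 600 s) band-pass highlighting change periods, and per-epoch
HR variation |Δhr| normalized by the sleep-period mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.preprocessing import MinMaxScaler

from .records import EpochTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# circadian model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightProcessParams:
    """Process L constants (Kronauer-standard defaults)."""

    alpha0: float = 0.05      # min⁻¹, activation rate at reference intensity
    beta: float = 0.0075      # min⁻¹, decay rate
    i0: float = 9500.0        # lux, reference intensity
    p: float = 0.5            # saturation exponent
    gain: float = 33.75       # drive gain G


@dataclass(frozen=True)
class CircadianParams:
    mu: float = 0.23          # van der Pol stiffness (best fit)
    tau_x: float = 24.2       # intrinsic oscillator period, hours
    k_b: float = 0.55         # direct light-effect gain
    light: LightProcessParams = field(default_factory=LightProcessParams)

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.tau_x <= 0:
            raise ValueError("mu and tau_x must be positive")

    @property
    def free_running_period(self) -> float:
        return 0.99669 * self.tau_x


@dataclass
class CircadianState:
    x: float = 0.0
    x_c: float = 0.0
    n_l: float = 0.0   # photoreceptor activation in [0, 1]
    b: float = 0.0     # current light drive

    def __post_init__(self) -> None:
        if not 0.0 <= self.n_l <= 1.0:
            raise ValueError(f"n_l must be in [0, 1], got {self.n_l}")


def cosine_clock(t_hours: np.ndarray | pd.Series) -> np.ndarray:
    """24 h cosine clock: C(t) = cos(2π t / 24), t in hours since onset."""
    t = np.asarray(t_hours, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("clock times must be finite")
    return np.cos(2.0 * np.pi * t / 24.0)


def activity_to_light(
    counts: EpochTable | np.ndarray,
    *,
    threshold: float = 0.0,
    i_active: float = 1000.0,
    i_dark: float = 0.0,
) -> np.ndarray:
    """Infer illuminance (lux) from activity counts by thresholding."""
    c = counts.frame.iloc[:, 0].to_numpy() if isinstance(counts, EpochTable) else np.asarray(counts, float)
    if (c < 0).any():
        raise ValueError("activity counts must be non-negative")
    return np.where(c > threshold, i_active, i_dark)


def _derivs(x: float, x_c: float, n_l: float, i_lux: float, p: CircadianParams):
    lp = p.light
    alpha = lp.alpha0 * (i_lux / lp.i0) ** lp.p if i_lux > 0 else 0.0
    b = lp.gain * alpha * (1.0 - n_l) * (1.0 - 0.4 * x) * (1.0 - 0.4 * x_c)
    w = (24.0 / (0.99669 * p.tau_x)) ** 2
    dx = (np.pi / 12.0) * (x_c + b)
    dxc = (np.pi / 12.0) * (p.mu * (x_c - 4.0 * x_c**3 / 3.0) - x * w + p.k_b * b)
    dn = 60.0 * (alpha * (1.0 - n_l) - lp.beta * n_l)  # per hour
    return dx, dxc, dn, b


def integrate_circadian(
    light: np.ndarray,
    params: CircadianParams | None = None,
    init: CircadianState | None = None,
    dt: float = 60.0,
) -> pd.DataFrame:
    """Fixed-step classical 4th-order integration of the circadian model.

    ``light`` gives illuminance (lux) per ``dt``-second step; the returned
    frame has one row per step with columns x, x_c, n_l, b.  The x column
    is the circadian-drive feature.
    """
    if params is None:
        params = CircadianParams()
    if init is None:
        init = CircadianState()
    if dt > 60.0:
        raise ValueError(f"dt must be ≤ 60 s, got {dt}")
    light = np.asarray(light, dtype=float)
    h = dt / 3600.0  # hours
    x, x_c, n_l = init.x, init.x_c, init.n_l
    out = np.empty((len(light), 4))
    for k, i_lux in enumerate(light):
        k1 = _derivs(x, x_c, n_l, i_lux, params)
        k2 = _derivs(x + h / 2 * k1[0], x_c + h / 2 * k1[1], n_l + h / 2 * k1[2], i_lux, params)
        k3 = _derivs(x + h / 2 * k2[0], x_c + h / 2 * k2[1], n_l + h / 2 * k2[2], i_lux, params)
        k4 = _derivs(x + h * k3[0], x_c + h * k3[1], n_l + h * k3[2], i_lux, params)
        x += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x_c += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        n_l += h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n_l = min(max(n_l, 0.0), 1.0)
        if not (np.isfinite(x) and np.isfinite(x_c)):
            raise FloatingPointError(f"circadian state non-finite at step {k}")
        out[k] = (x, x_c, n_l, k1[3])
    return pd.DataFrame(out, columns=["x", "x_c", "n_l", "b"])


def free_running_period(trajectory: pd.DataFrame, dt: float) -> float:
    """Measure the oscillation period (hours) from upward zero crossings of x."""
    x = trajectory["x"].to_numpy()
    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if len(up) < 2:
        raise ValueError("trajectory too short to measure a period")
    # linear interpolation of each crossing instant
    frac = -x[up] / (x[up + 1] - x[up])
    times = (up + frac) * dt / 3600.0
    return float(np.mean(np.diff(times)))


# ---------------------------------------------------------------------------
# activity counts from raw acceleration
# ---------------------------------------------------------------------------

def acceleration_to_counts(
    accel: pd.DataFrame | np.ndarray,
    fs: float,
    epoch: float = 30.0,
    *,
    highpass_hz: float = 0.25,
    scale: float = 1000.0,
) -> np.ndarray:
    """Epoch activity counts from triaxial acceleration.

    Each axis is high-pass filtered (DC/gravity removal), the magnitude of
    the filtered signal rectified, and the per-epoch maximum scaled to
    integer counts — the shape of the standard actigraphy-count recipe.
    """
    if fs < 10.0:
        raise ValueError(f"sampling rate must be ≥ 10 Hz, got {fs}")
    a = accel.to_numpy() if isinstance(accel, pd.DataFrame) else np.asarray(accel, float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("acceleration must have three channels")
    n_per_epoch = int(round(fs * epoch))
    if len(a) < n_per_epoch:
        raise ValueError("fewer samples than one epoch")
    sos = sps.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, a, axis=0)
    mag = np.linalg.norm(filt, axis=1)
    n_epochs = len(mag) // n_per_epoch
    peaks = mag[: n_epochs * n_per_epoch].reshape(n_epochs, n_per_epoch).max(axis=1)
    return np.floor(peaks * scale).astype(int)


# ---------------------------------------------------------------------------
# convolution filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Gaussian or difference-of-Gaussians smoothing specification.

    ``sigma``/``sigma2`` are in samples unless ``sample_interval`` is set,
    in which case they are seconds on that grid.
    """

    kind: str = "gaussian"  # or "difference_of_gaussians"
    sigma: float = 50.0
    sigma2: float | None = None
    truncation: float = 4.0
    padding: str = "reflect"  # reflect | zero | nearest
    sample_interval: float | None = None  # seconds per sample, if sigma in s

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "difference_of_gaussians":
            if self.sigma2 is None or self.sigma2 <= self.sigma:
                raise ValueError("DoG requires sigma2 > sigma")
        elif self.kind != "gaussian":
            raise ValueError(f"unknown filter kind {self.kind!r}")

    def sigmas_in_samples(self) -> tuple[float, float | None]:
        f = 1.0 / self.sample_interval if self.sample_interval else 1.0
        return self.sigma * f, None if self.sigma2 is None else self.sigma2 * f


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def kernel(spec: FilterSpec) -> np.ndarray:
    """The (unit-sum Gaussian or zero-sum DoG) convolution kernel."""
    s1, s2 = spec.sigmas_in_samples()
    radius = int(np.ceil(spec.truncation * (s2 if s2 else s1)))
    g1 = _gaussian_kernel(s1, radius)
    if spec.kind == "gaussian":
        return g1
    return g1 - _gaussian_kernel(s2, radius)


def convolve(series: np.ndarray | pd.Series, spec: FilterSpec) -> np.ndarray:
    """Convolve a uniform series with the specified kernel.

    Gaussian kernels are unit-sum (constants pass through unchanged); DoG
    kernels are zero-sum (constants map to zero).  Default reflect padding.
    """
    y = np.asarray(series, dtype=float)
    k = kernel(spec)
    radius = len(k) // 2
    if len(y) < len(k):
        raise ValueError(f"series of length {len(y)} shorter than kernel ({len(k)})")
    mode = {"reflect": "reflect", "zero": "constant", "nearest": "edge"}[spec.padding]
    padded = np.pad(y, radius, mode=mode)
    return np.convolve(padded, k, mode="valid")


# ---------------------------------------------------------------------------
# heart-rate channels
# ---------------------------------------------------------------------------

def hr_preprocess(
    hr: EpochTable, smooth: FilterSpec | None = None
) -> pd.Series:
    """Interpolate heart rate onto a 1 s grid and Gaussian-smooth it.

    Default smoothing reuses the σ = 120 s Gaussian of the DoG band (the
    recipe names no separate smoothing width).
    """
    frame = hr.frame.iloc[:, 0]
    if len(frame) < 2:
        logger.warning("hr_preprocess: single sample, constant extension")
        idx = pd.date_range(frame.index[0], periods=hr.interval, freq="1s")
        return pd.Series(frame.iloc[0], index=idx, name="hr_1s")
    t = frame.index.asi8 / 1e9
    grid = np.arange(t[0], t[-1] + 1.0)
    vals = np.interp(grid, t, frame.to_numpy(dtype=float))
    if smooth is None:
        smooth = FilterSpec(kind="gaussian", sigma=120.0, sample_interval=1.0)
    smoothed = convolve(vals, smooth) if len(vals) >= len(kernel(smooth)) else vals
    idx = pd.to_datetime((grid * 1e9).astype("int64"))
    return pd.Series(smoothed, index=idx, name="hr_1s")


def hr_variation(hr: np.ndarray | pd.Series, sleep_period_mean: float) -> np.ndarray:
    """Consecutive absolute HR difference over the sleep-period mean.

    v_i = |hr_{i+1} − hr_i| / mean; output is one element shorter than
    the input.
    """
    if sleep_period_mean <= 0:
        raise ValueError("sleep_period_mean must be positive")
    h = np.asarray(hr, dtype=float)
    return np.abs(np.diff(h)) / sleep_period_mean


def log_positify(y: np.ndarray | pd.Series) -> np.ndarray:
    """Order-preserving positive rescale: log2(y + 1 − min(y)); min → 0."""
    v = np.asarray(y, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(v)):
        raise ValueError("series must be finite")
    return np.log2(v + 1.0 - v.min())


def minmax_scale(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, MinMaxScaler]:
    """Columnwise (v−min)/(max−min) with train-fitted bounds.

    Values outside the train range extrapolate beyond [0, 1] (no clipping);
    constant columns map to 0.  Returns (scaled train, scaled apply_to,
    fitted scaler).
    """
    if train.empty:
        raise ValueError("empty training table")
    scaler = MinMaxScaler(clip=False)
    tr = pd.DataFrame(scaler.fit_transform(train), index=train.index, columns=train.columns)
    if apply_to is None:
        return tr, tr, scaler
    n_outside = int(((apply_to < scaler.data_min_) | (apply_to > scaler.data_max_)).sum().sum())
    if n_outside:
        logger.info("minmax_scale: %d values outside the train range", n_outside)
    ap = pd.DataFrame(
        scaler.transform(apply_to), index=apply_to.index, columns=apply_to.columns
    )
    return tr, ap, scaler


# ---------------------------------------------------------------------------
# per-night feature assembly
# ---------------------------------------------------------------------------

def night_feature_table(night, params: CircadianParams | None = None) -> EpochTable:
    """Assemble the modelling feature table for one synthetic night.

    Columns: time (hours since night start), cosine, circadian (oscillator
    x driven by activity-inferred light), hr, hr_var, steps, plus the stage
    label and a night identifier for grouping.
    """
    hyp = night.hypnogram
    idx = hyp.timestamps
    t_h = (idx.asi8 - idx.asi8[0]) / 3.6e12
    hr = night.heart_rate.frame["hr"].to_numpy()
    steps = night.steps.frame["steps"].to_numpy()
    light = activity_to_light(steps)
    dt = float(hyp.interval)
    traj = integrate_circadian(light, params, CircadianState(x=1.0, x_c=0.0), dt=dt)
    hv = np.r_[0.0, hr_variation(hr, float(np.mean(hr)))]
    frame = pd.DataFrame(
        {
            "time": t_h,
            "cosine": cosine_clock(t_h),
            "circadian": traj["x"].to_numpy(),
            "hr": hr,
            "hr_var": hv,
            "steps": steps,
            "stage": hyp.frame["stage"].to_numpy(),
            "night_id": str(idx[0].date()),
        },
        index=idx,
    )
    return EpochTable(frame, hyp.interval)
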