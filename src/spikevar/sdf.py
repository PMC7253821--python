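"""Peri-event alignment and spike-density-function (SDF) estimation.

The SDF replaces every spike by a unit-area Gaussian kernel (SD 30 ms by
default) and sums the kernels, giving a continuous firing-rate estimate in
spikes/s on a uniform time grid.  Averaging SDF rows across trials gives the
trial-mean rate; the across-trial variance of the SDF is the raw material of
the normalized-variance statistic in :mod:`spikevar.variability`.

Edge handling: each trial's SDF is computed on a grid padded by
``truncation * sigma`` on both sides of the requested window and then
cropped, so spikes just outside the window still contribute their kernel
mass inside it.  The ms -> s conversion factor 1000 appears here only, in
:func:`compute_sdf`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .spikegen import SpikeTrain, TrialSet

__all__ = ["KernelSpec", "SDFMatrix", "gaussian_kernel", "align_trials", "compute_sdf", "mean_sdf"]

#: ms -> s conversion applied once when scaling SDF values to spikes/s.
MS_PER_S = 1000.0


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian smoothing kernel: SD ``sigma`` ms, grid step ``dt`` ms,
    support truncated at ``truncation`` multiples of sigma."""

    sigma: float = 30.0
    dt: float = 1.0
    truncation: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0 ms")
        if self.dt <= 0:
            raise ValueError("dt must be > 0 ms")
        if self.truncation < 3:
            raise ValueError("truncation must be >= 3 sigma")

    @property
    def half_width(self) -> float:
        """Half support of the truncated kernel, ms."""
        return self.truncation * self.sigma


@dataclass(frozen=True)
class SDFMatrix:
    """Trials x time-grid matrix of smoothed firing rates (spikes/s)."""

    values: np.ndarray
    time_grid: np.ndarray
    kernel: KernelSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "time_grid", g)
        if v.ndim != 2 or v.shape[1] != g.size:
            raise ValueError("values must be n_trials x len(time_grid)")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def gaussian_kernel(spec: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Discrete unit-area Gaussian kernel on lags ``-T..T`` step ``dt``.

    Returns ``(lags_ms, k)`` with ``k`` in 1/ms, renormalized so that
    ``dt * sum(k) == 1`` exactly despite truncation of the tails.
    """
    n = int(np.ceil(spec.half_width / spec.dt))
    lags = np.arange(-n, n + 1) * spec.dt
    k = np.exp(-0.5 * (lags / spec.sigma) ** 2)
    k /= spec.dt * k.sum()
    return lags, k


def align_trials(ts: TrialSet, event) -> TrialSet:
    """Re-express spike times relative to a per-trial event (time 0 = event).

    ``event`` is ``"target_onset"`` (read from the task-epoch profile), a
    scalar ms value applied to every trial, or a sequence of per-trial event
    times.  The returned set's ``[t_start, t_stop)`` is the intersection of
    the shifted trial supports.
    """
    if isinstance(event, str):
        if event != "target_onset":
            raise ValueError(f"unknown event {event!r}")
        if ts.profile is None or ts.profile.target_onset is None:
            raise ValueError("profile has no target_onset to align to")
        events = np.full(ts.n_trials, float(ts.profile.target_onset))
    else:
        events = np.asarray(event, dtype=float)
        if events.ndim == 0:
            events = np.full(ts.n_trials, float(events))
    if events.size != ts.n_trials:
        missing = ts.n_trials - events.size
        raise ValueError(f"need one event time per trial ({missing} trial(s) missing)")
    bad = np.nonzero(~((events >= 0) & (events <= ts.duration) & np.isfinite(events)))[0]
    if bad.size:
        raise ValueError(f"event time missing or out of range for trial(s) {bad.tolist()}")
    shifted = tuple(
        _shift(tr, e) for tr, e in zip(ts.trials, events)
    )
    return TrialSet(
        trials=shifted,
        profile=ts.profile,
        noise=ts.noise,
        offsets=ts.offsets,
        seed=ts.seed,
        align_event=float(np.mean(events)),
        t_start=float(-np.min(events)),
        t_stop=float(ts.duration - np.max(events)),
    )


def _shift(tr: SpikeTrain, e: float) -> SpikeTrain:
    # bypass [0, duration) validation: aligned times are relative to the event
    out = SpikeTrain.__new__(SpikeTrain)
    object.__setattr__(out, "times", tr.times - e)
    object.__setattr__(out, "duration", tr.duration)
    return out


def compute_sdf(
    ts: TrialSet, spec: KernelSpec = KernelSpec(), window: tuple[float, float] | None = None
) -> SDFMatrix:
    """Kernel-smoothed firing rate per trial on a uniform grid, spikes/s.

    Row i is the sum over trial-i spikes of the unit-area Gaussian centered
    at each spike.  The grid covers ``[window[0], window[1])`` with step
    ``spec.dt``; the default window is the trial set's full support.
    """
    if window is None:
        window = (ts.t_start, ts.t_stop)
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    if t0 < ts.t_start - 1e-9 or t1 > ts.t_stop + 1e-9:
        raise ValueError("window outside the trial set's time support")
    pad_bins = int(np.ceil(spec.half_width / spec.dt))
    n_bins = int(np.round((t1 - t0) / spec.dt))
    if n_bins < 1:
        raise ValueError("window shorter than dt")
    edges = t0 + (np.arange(-pad_bins, n_bins + pad_bins + 1)) * spec.dt
    counts = np.stack(
        [np.histogram(tr.times, bins=edges)[0] for tr in ts.trials]
    ).astype(float)
    _, k = gaussian_kernel(spec)
    smoothed = fftconvolve(counts, k[None, :], mode="same", axes=1)
    values = np.clip(smoothed[:, pad_bins : pad_bins + n_bins], 0.0, None) * MS_PER_S
    grid = t0 + (np.arange(n_bins) + 0.5) * spec.dt
    return SDFMatrix(values=values, time_grid=grid, kernel=spec)


def mean_sdf(m: SDFMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise across-trial mean and unbiased (n-1) variance, spikes/s."""
    if m.n_trials < 2:
        raise ValueError("need >= 2 trials for across-trial variance")
    return m.values.mean(axis=0), m.values.var(axis=0, ddof=1)
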