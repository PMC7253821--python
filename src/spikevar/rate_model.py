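"""Deterministic trial rate profiles and the trial-to-trial rate noise model.

A :class:`RateProfile` is the deterministic instantaneous firing rate
``lambda(t)`` (spikes/s) a neuron would follow on every trial of a reaching
task.  Two shapes are supported: a constant rate, and a task-epoch profile
that sits at a baseline rate until target onset and then ramps linearly to a
peak rate — the canonical stimulus-locked rise of motor-preparatory activity.

Trial-to-trial variability beyond Poisson spiking is modelled by
:class:`NoiseSpec`: each trial draws a single Gaussian offset ``eta_i ~
N(0, sigma^2)`` (spikes/s) that shifts the whole profile for that trial,
giving the doubly stochastic ("noisy Poisson") process.  An additive,
per-trial-constant offset makes the count Fano factor ``1 + sigma^2 w /
lambda``, which *decreases* with rate — the inverse variability/rate relation
this package reproduces.  Rates are clipped at zero by default because an
intensity cannot be negative.

All times are milliseconds, all rates spikes per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["RateProfile", "NoiseSpec", "TrialRate", "evaluate_rate", "draw_trial_rate"]

_PROFILE_KINDS = ("constant", "task_epoch")
_NOISE_KINDS = ("none", "additive_offset")


@dataclass(frozen=True)
class RateProfile:
    """Deterministic instantaneous firing rate over one trial.

    Parameters
    ----------
    kind : {"constant", "task_epoch"}
    duration : float
        Trial length in ms, > 0.
    baseline_rate : float
        Rate (spikes/s) before target onset, or everywhere for ``constant``.
    peak_rate, target_onset, rise_time : float, optional
        ``task_epoch`` only: rate ramps linearly from ``baseline_rate`` to
        ``peak_rate`` over ``[target_onset, target_onset + rise_time]`` ms.
    """

    kind: str
    duration: float
    baseline_rate: float
    peak_rate: float | None = None
    target_onset: float | None = None
    rise_time: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}; expected one of {_PROFILE_KINDS}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0 ms")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0 spikes/s")
        if self.kind == "task_epoch":
            if self.peak_rate is None or self.target_onset is None or self.rise_time is None:
                raise ValueError("task_epoch profile requires peak_rate, target_onset and rise_time")
            if self.peak_rate < 0:
                raise ValueError("peak_rate must be >= 0 spikes/s")
            if not 0 <= self.target_onset <= self.duration:
                raise ValueError("target_onset must lie within [0, duration]")
            if self.rise_time < 0 or self.target_onset + self.rise_time > self.duration:
                raise ValueError("target_onset + rise_time must be <= duration")

    @property
    def max_rate(self) -> float:
        """Upper bound of the profile, used as the thinning ceiling."""
        if self.kind == "constant":
            return self.baseline_rate
        return max(self.baseline_rate, float(self.peak_rate))

    def __call__(self, t):
        return evaluate_rate(self, t)


def evaluate_rate(profile: RateProfile, t):
    """Evaluate ``lambda(t)`` (spikes/s) at time(s) ``t`` ms into the trial.

    ``t`` may be a scalar or array; every element must lie in
    ``[0, duration)``.  The task-epoch profile is baseline before onset,
    a linear ramp over the rise interval, and peak after it.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= profile.duration):
        raise ValueError(f"time outside [0, {profile.duration}) ms")
    if profile.kind == "constant":
        out = np.full_like(t_arr, profile.baseline_rate)
    else:
        onset = float(profile.target_onset)
        rise = float(profile.rise_time)
        peak = float(profile.peak_rate)
        if rise > 0:
            frac = np.clip((t_arr - onset) / rise, 0.0, 1.0)
        else:
            frac = (t_arr >= onset).astype(float)
        out = profile.baseline_rate + frac * (peak - profile.baseline_rate)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-trial Gaussian perturbation of the rate profile.

    ``kind="none"`` leaves the profile untouched.  ``kind="additive_offset"``
    draws one offset ``eta_i ~ N(0, sigma^2)`` per trial and adds it to the
    rate at every time point of that trial.  With ``clip_at_zero`` the
    realized rate is ``max(0, lambda(t) + eta_i)``.
    """

    sigma: float = 0.0
    kind: str = "none"
    clip_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_NOISE_KINDS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0 spikes/s")


@dataclass(frozen=True)
class TrialRate:
    """One trial's realized rate function: profile plus recorded offset."""

    profile: RateProfile
    offset: float
    clip_at_zero: bool = True

    @property
    def max_rate(self) -> float:
        return max(0.0, self.profile.max_rate + max(0.0, self.offset))

    def __call__(self, t):
        r = np.asarray(evaluate_rate(self.profile, t), dtype=float) + self.offset
        if self.clip_at_zero:
            r = np.maximum(r, 0.0)
        elif np.any(r < 0):
            raise ValueError("realized rate negative and clip_at_zero is off")
        return r if r.ndim else float(r)


def draw_trial_rate(
    profile: RateProfile, noise: NoiseSpec, rng: np.random.Generator
) -> TrialRate:
    """Draw one trial's rate function ``lambda_i(t) = max(0, lambda(t) + eta_i)``.

    The Gaussian offset ``eta_i`` is drawn once and held constant over the
    trial; it is recorded on the returned :class:`TrialRate` so provenance
    can be serialized.  ``kind="none"`` returns the profile unchanged with
    offset 0 (and consumes no random numbers).
    """
    if noise.kind == "none" or noise.sigma == 0.0:
        offset = 0.0
    else:
        offset = float(rng.normal(0.0, noise.sigma))
    return TrialRate(profile=profile, offset=offset, clip_at_zero=noise.clip_at_zero)
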