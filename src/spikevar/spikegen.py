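"""Poisson spike-train generation and trial-set packaging.

Spike trains are realizations of (in)homogeneous Poisson point processes.
Homogeneous trains use the classic two-step construction (Poisson count,
then i.i.d. uniform times); inhomogeneous trains use Lewis–Shedler thinning
against a rate ceiling, which is exact for bounded rate functions.

A :class:`TrialSet` bundles the repeated trials of one simulated "neuron"
together with full provenance (profile, noise spec, per-trial offsets, root
seed).  Per-trial randomness comes from independent substreams derived from
the root seed via ``numpy``'s ``SeedSequence(seed, spawn_key=(i,))``, so
trial ``i`` is reproducible regardless of how many trials are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .rate_model import NoiseSpec, RateProfile, TrialRate, draw_trial_rate

__all__ = [
    "SpikeTrain",
    "TrialSet",
    "poisson_pmf",
    "generate_homogeneous",
    "generate_inhomogeneous",
    "simulate_trialset",
    "trial_rng",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) of one trial, in ``[0, duration)``."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if not self.duration > 0:
            raise ValueError("duration must be > 0 ms")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be non-decreasing")
            if t[0] < 0 or t[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TrialSet:
    """Aligned collection of per-trial spike trains with provenance.

    ``t_start``/``t_stop`` give the common time support of the trials in the
    current clock: ``[0, duration)`` for a freshly simulated set, shifted
    after peri-event alignment (time 0 = event).  ``align_event`` records the
    event time, in the original trial clock, that time 0 refers to.
    """

    trials: tuple
    profile: RateProfile | None
    noise: NoiseSpec | None
    offsets: np.ndarray
    seed: int | None
    align_event: float = 0.0
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if not self.trials:
            raise ValueError("TrialSet needs at least one trial")
        durations = {tr.duration for tr in self.trials}
        if len(durations) != 1:
            raise ValueError("all trials must share one duration")
        if len(self.offsets) != len(self.trials):
            raise ValueError("offsets must have one entry per trial")
        if self.t_stop is None:
            object.__setattr__(self, "t_stop", self.t_start + self.duration)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        return self.trials[0].duration

    def spike_times(self) -> list[np.ndarray]:
        return [tr.times for tr in self.trials]


def poisson_pmf(count: int, mu: float) -> float:
    """P(X = count) for X ~ Poisson(mu): ``exp(-mu) mu^k / k!``.

    Evaluated in log space (via :mod:`scipy.stats`) so large counts do not
    overflow ``mu**k`` or ``k!``.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    k = np.asarray(count)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
        raise ValueError("count must be a non-negative integer")
    out = stats.poisson.pmf(k, mu)
    return float(out) if np.ndim(count) == 0 else out


def generate_homogeneous(rate: float, duration: float, rng: np.random.Generator) -> SpikeTrain:
    """Homogeneous Poisson train at ``rate`` spikes/s over ``duration`` ms.

    The spike count is Poisson with mean ``rate * duration / 1000`` and,
    conditional on the count, times are i.i.d. uniform on ``[0, duration)``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0 spikes/s")
    n = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(times=times, duration=duration)


def generate_inhomogeneous(
    rate_fn, duration: float, rng: np.random.Generator, rate_max: float | None = None
) -> SpikeTrain:
    """Inhomogeneous Poisson train by thinning a homogeneous one.

    Candidates are generated at the ceiling ``rate_max`` (taken from
    ``rate_fn.max_rate`` when not given) and kept with probability
    ``rate_fn(t) / rate_max``; counts in any window ``[a, b)`` are then
    Poisson with mean ``integral of lambda / 1000``.
    """
    if rate_max is None:
        rate_max = getattr(rate_fn, "max_rate", None)
    if rate_max is None:
        raise ValueError("rate_fn must expose max_rate or rate_max must be given")
    if rate_max < 0:
        raise ValueError("rate ceiling must be >= 0")
    if rate_max == 0:
        return SpikeTrain(times=np.empty(0), duration=duration)
    candidates = generate_homogeneous(rate_max, duration, rng)
    if len(candidates) == 0:
        return SpikeTrain(times=candidates.times, duration=duration)
    lam = np.asarray(rate_fn(candidates.times), dtype=float)
    if np.any(lam < 0) or np.any(lam > rate_max * (1 + 1e-12)):
        raise ValueError("rate_fn must stay within [0, rate_max]")
    keep = rng.uniform(size=len(candidates)) < lam / rate_max
    return SpikeTrain(times=candidates.times[keep], duration=duration)


def trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    """Independent, reproducible substream for one trial of a root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(trial_index,)))


def simulate_trialset(
    profile: RateProfile,
    noise: NoiseSpec,
    n_trials: int,
    seed: int,
    align_event: float = 0.0,
) -> TrialSet:
    """Simulate ``n_trials`` repetitions of the (noisy) Poisson process.

    Each trial first draws its rate function (profile plus recorded Gaussian
    offset), then a spike train from it by thinning.  Trial ``i`` uses the
    substream ``trial_rng(seed, i)``, so the same (seed, i) always yields
    the same trial.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 (across-trial variance undefined otherwise)")
    trials = []
    offsets = np.empty(n_trials)
    for i in range(n_trials):
        rng = trial_rng(seed, i)
        tr_rate = draw_trial_rate(profile, noise, rng)
        offsets[i] = tr_rate.offset
        trials.append(generate_inhomogeneous(tr_rate, profile.duration, rng))
    return TrialSet(
        trials=tuple(trials),
        profile=profile,
        noise=noise,
        offsets=offsets,
        seed=seed,
        align_event=align_event,
    )
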