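"""Deterministic synthetic datasets emulating the reaching-task simulations.

Each fixture is a named (config, trial set) pair with documented expected
statistics, generated entirely from a seed: 100 trials of 1000 ms, either a
constant 20 spikes/s rate or a task-epoch profile rising from 5 to 45
spikes/s at a 400 ms target onset, with or without per-trial Gaussian rate
noise.  The noisy constant fixture uses sigma = 10 spikes/s so its expected
full-window count Fano factor, 1 + sigma^2 w / lambda = 6, sits far from the
Poisson value of 1; the noisy task-epoch fixture uses sigma = 5 spikes/s so
the level-binned NV spans a clear inverse rate relation.
"""

from __future__ import annotations

from .io import RunConfig
from .rate_model import NoiseSpec, RateProfile
from .spikegen import TrialSet, simulate_trialset

__all__ = ["FIXTURE_NAMES", "make_fixture"]

_CONSTANT = RateProfile(kind="constant", duration=1000.0, baseline_rate=20.0)
_TASK_EPOCH = RateProfile(kind="task_epoch", duration=1000.0, baseline_rate=5.0,
                          peak_rate=45.0, target_onset=400.0, rise_time=100.0)

_SPECS = {
    "pure_constant": (_CONSTANT, NoiseSpec()),
    "noisy_constant": (_CONSTANT, NoiseSpec(sigma=10.0, kind="additive_offset")),
    "task_epoch_pure": (_TASK_EPOCH, NoiseSpec()),
    "task_epoch_noisy": (_TASK_EPOCH, NoiseSpec(sigma=5.0, kind="additive_offset")),
}

FIXTURE_NAMES = tuple(_SPECS)


def make_fixture(name: str, seed: int, n_trials: int = 100) -> tuple[RunConfig, TrialSet]:
    """Build the named fixture: its run config and the simulated trial set.

    Expected statistics (by construction): ``pure_constant`` has mean count
    20 per trial and count Fano 1; ``noisy_constant`` has full-window Fano
    ~6; the task-epoch fixtures have post-onset mean rate above pre-onset.
    """
    if name not in _SPECS:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
    profile, noise = _SPECS[name]
    config = RunConfig(profile=profile, noise=noise, n_trials=n_trials, seed=seed)
    ts = simulate_trialset(profile, noise, n_trials=n_trials, seed=seed)
    return config, ts
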