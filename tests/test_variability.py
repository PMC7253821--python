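import numpy as np
import pytest

from spikevar import (KernelSpec, NVConstants, NoiseSpec, RateProfile, SDFMatrix,
                      SpikeTrain, TrialSet, align_trials, compute_sdf, count_fano,
                      kernel_correction, matched_window_ms, mean_sdf, nv_series,
                      pool_nv, rate_level_nv, simulate_trialset)

CONST20 = RateProfile(kind="constant", duration=1000.0, baseline_rate=20.0)


def _matrix(rows, spec=KernelSpec()):
    rows = np.asarray(rows, float)
    grid = np.arange(rows.shape[1]) + 0.5
    return SDFMatrix(values=rows, time_grid=grid, kernel=spec)


def _empty_trialset(n=5, duration=1000.0):
    trials = tuple(SpikeTrain(times=np.empty(0), duration=duration) for _ in range(n))
    return TrialSet(trials=trials, profile=None, noise=None, offsets=np.zeros(n), seed=None)


# ---------------------------------------------------------------- nv_series

def test_nv_is_one_when_variance_equals_mean():
    # rows {1, 0}: pointwise mean 0.5 and (n-1)-variance 0.5, so with
    # eps == eps' the regularized ratio is exactly 1
    nv = nv_series(_matrix([[1.0, 1.0], [0.0, 0.0]]), mode="raw_eq1")
    assert np.allclose(nv.nv, 1.0)


def test_nv_regularizer_only_limit():
    """All-empty trials: NV = k*eps / (k*eps') = 1."""
    nv = nv_series(compute_sdf(_empty_trialset()), mode="raw_eq1")
    assert np.allclose(nv.nv, 1.0)


def test_raw_mode_of_poisson_equals_kernel_constant(pure_100):
    """Uncorrected variance-to-mean of a smoothed Poisson process sits at the
    kernel constant (~9.4 for the 30 ms Gaussian), not at 1."""
    m = compute_sdf(pure_100)
    raw = nv_series(m, mode="raw_eq1").time_mean
    cal = nv_series(m, mode="calibrated").time_mean
    c = kernel_correction(m.kernel)
    assert raw == pytest.approx(c * cal, rel=0.02)
    assert raw > 5.0 and abs(cal - 1.0) < 0.15


def test_nv_invariant_to_trial_permutation(noisy_100):
    m = compute_sdf(noisy_100)
    rng = np.random.default_rng(0)
    perm = SDFMatrix(values=m.values[rng.permutation(m.n_trials)],
                     time_grid=m.time_grid, kernel=m.kernel)
    assert np.allclose(nv_series(m).nv, nv_series(perm).nv)


def test_nv_requires_two_trials():
    one = SDFMatrix(values=np.ones((1, 4)), time_grid=np.arange(4.0), kernel=KernelSpec())
    with pytest.raises(ValueError):
        nv_series(one)


def test_nv_refinement_stability(noisy_100):
    """Halving dt changes the time-mean NV by < 1%."""
    tm = [nv_series(compute_sdf(noisy_100, KernelSpec(dt=dt))).time_mean
          for dt in (1.0, 0.5)]
    assert abs(tm[0] - tm[1]) / tm[0] < 0.01


# ---------------------------------------------------------------- calibration

def test_kernel_correction_brute_force_poisson():
    """10_000 Poisson trials: calibrated NV in [0.98, 1.02] at every scale."""
    ts = simulate_trialset(CONST20, NoiseSpec(), 10_000, seed=2)
    nv = nv_series(compute_sdf(ts, window=(150.0, 850.0)))
    assert 0.98 < nv.time_mean < 1.02


def test_kernel_correction_delta_limit():
    """A near-delta kernel reduces to the 1 ms count-bin Fano scale (1000)."""
    c = kernel_correction(KernelSpec(sigma=0.2, dt=1.0))
    assert c == pytest.approx(1000.0, rel=0.01)


def test_kernel_correction_scales_inversely_with_sigma():
    c30 = kernel_correction(KernelSpec(sigma=30.0))
    c60 = kernel_correction(KernelSpec(sigma=60.0))
    assert c60 / c30 == pytest.approx(0.5, abs=1e-3)
    assert c30 == pytest.approx(1000.0 / (2 * 30.0 * np.sqrt(np.pi)), rel=1e-4)
    assert matched_window_ms(KernelSpec(sigma=30.0)) == pytest.approx(
        2 * 30.0 * np.sqrt(np.pi), rel=1e-4)


# ---------------------------------------------------------------- count_fano

def test_count_fano_zero_variance():
    times = np.arange(100.0, 900.0, 100.0)
    trials = tuple(SpikeTrain(times=times.copy(), duration=1000.0) for _ in range(10))
    ts = TrialSet(trials=trials, profile=None, noise=None, offsets=np.zeros(10), seed=None)
    f = count_fano(ts, window=200.0, step=50.0)
    c = f.constants
    expected_floor = c.k * c.eps / (c.k * c.eps_prime + 1.6)  # 1.6 spikes per 200 ms
    assert f.nv.max() < 0.01 and f.nv.min() >= 0.0
    assert f.nv[len(f.nv) // 2] == pytest.approx(expected_floor, rel=0.5)


def test_count_fano_poisson_unity():
    ts = simulate_trialset(CONST20, NoiseSpec(), 1000, seed=6)
    f = count_fano(ts, window=100.0, step=10.0)
    assert f.time_mean == pytest.approx(1.0, abs=0.05)


def test_count_fano_window_validation(pure_100):
    with pytest.raises(ValueError):
        count_fano(pure_100, window=2000.0)
    with pytest.raises(ValueError):
        count_fano(pure_100, window=0.5)


# ---------------------------------------------------------------- rate levels

def test_constant_rate_occupies_top_level_only(pure_100):
    m = compute_sdf(pure_100, window=(150.0, 850.0))
    nv = nv_series(m)
    rate, _ = mean_sdf(m)
    levels = rate_level_nv(nv, rate)
    assert levels.n[0] > 0
    # empty levels reported with n=0, not dropped
    assert len(levels.n) == 3 and levels.n[2] == 0 and np.isnan(levels.nv_mean[2])


def test_additive_noise_closed_form_per_rate():
    """Calibrated NV of a noisy-rate Poisson process matches
    1 + sigma^2/(c * lambda): higher rate, lower NV."""
    sigma, c = 5.0, kernel_correction(KernelSpec())
    means = {}
    for lam in (15.0, 40.0):
        prof = RateProfile(kind="constant", duration=1000.0, baseline_rate=lam)
        reps = [nv_series(compute_sdf(
            simulate_trialset(prof, NoiseSpec(sigma=sigma, kind="additive_offset"),
                              500, seed=s),
            window=(150.0, 850.0))).time_mean for s in range(6)]
        means[lam] = np.mean(reps)
    for lam, got in means.items():
        assert got == pytest.approx(1.0 + sigma**2 / (c * lam), abs=0.04)
    assert means[15.0] > means[40.0]


def test_rate_level_requires_positive_max():
    nv = nv_series(compute_sdf(_empty_trialset()))
    with pytest.raises(ValueError):
        rate_level_nv(nv, np.zeros_like(nv.nv))


# ---------------------------------------------------------------- pooling

def test_pool_single_and_identical_series(noisy_100):
    nv = nv_series(compute_sdf(noisy_100))
    single = pool_nv([nv])
    assert np.allclose(single.nv, nv.nv) and np.allclose(single.se, 0.0)
    two = pool_nv([nv, nv])
    assert np.allclose(two.nv, nv.nv) and np.allclose(two.se, 0.0)


def test_pool_rejects_mismatched_grids(pure_100):
    a = nv_series(compute_sdf(pure_100))
    b = nv_series(compute_sdf(pure_100, window=(100.0, 900.0)))
    with pytest.raises(ValueError):
        pool_nv([a, b])


def test_pooled_units_show_post_onset_nv_decline():
    """Across simulated units sharing the ramp profile + rate noise, pooled
    NV after target onset drops below the pre-onset level."""
    prof = RateProfile(kind="task_epoch", duration=1000.0, baseline_rate=5.0,
                       peak_rate=45.0, target_onset=400.0, rise_time=100.0)
    noise = NoiseSpec(sigma=5.0, kind="additive_offset")
    series = []
    for unit in range(20):
        ts = align_trials(simulate_trialset(prof, noise, 100, seed=100 + unit),
                          "target_onset")
        series.append(nv_series(compute_sdf(ts)))
    pooled = pool_nv(series)
    t = pooled.time_grid
    pre = pooled.nv[(t >= -300) & (t < 0)].mean()
    post = pooled.nv[(t >= 0) & (t < 300)].mean()
    assert post < pre
    assert pooled.se is not None and np.all(pooled.se >= 0)
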