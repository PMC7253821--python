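"""The simulate -> analyze -> report pipeline behind the CLI.

Each step is a plain function over the library types so it can be driven
from Python as easily as from the shell.  Every output directory gets a
``run.json`` log recording the config hash, so a run is identifiable and
reproducible from its artifacts alone.  On failure, files already written
to the output directory by the failing step are removed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as svio
from .io import RunConfig
from .sdf import KernelSpec, align_trials, compute_sdf, mean_sdf
from .spikegen import TrialSet, simulate_trialset
from .variability import (NVConstants, count_fano, matched_window_ms, nv_series,
                          rate_level_nv)

__all__ = ["run_simulate", "run_analyze", "run_report"]


def _cleanup_on_error(step):
    def wrapper(*args, **kwargs):
        created: list[Path] = []
        try:
            return step(*args, created=created, **kwargs)
        except Exception:
            for p in created:
                if p.exists():
                    p.unlink()
            raise
    wrapper.__name__ = step.__name__
    wrapper.__doc__ = step.__doc__
    return wrapper


@_cleanup_on_error
def run_simulate(config: RunConfig, out_dir: str | Path, created=None) -> TrialSet:
    """Simulate the configured trial set and write it to ``out_dir``."""
    out = Path(out_dir)
    ts = simulate_trialset(config.profile, config.noise, config.n_trials, config.seed)
    svio.write_trialset(ts, out)
    created += [out / svio.SPIKES_FILE, out / svio.META_FILE]
    config.to_yaml(out / "config.yaml")
    created.append(out / "config.yaml")
    _log(out, created, step="simulate", config=config)
    return ts


@_cleanup_on_error
def run_analyze(
    in_dir: str | Path,
    out_dir: str | Path | None = None,
    kernel: KernelSpec = KernelSpec(),
    constants: NVConstants = NVConstants(),
    mode: str = "calibrated",
    created=None,
) -> dict:
    """Align, smooth and compute NV for a stored trial set.

    Task-epoch sets are aligned to target onset (time 0 = onset) before
    smoothing.  Writes the SDF matrix, the tidy NV table, the trial-mean
    rate and the rate-level NV summary to ``out_dir``.
    """
    in_dir = Path(in_dir)
    out = Path(out_dir) if out_dir is not None else in_dir
    out.mkdir(parents=True, exist_ok=True)
    ts = svio.read_trialset(in_dir)
    if ts.profile is not None and ts.profile.kind == "task_epoch":
        ts = align_trials(ts, "target_onset")
    m = compute_sdf(ts, kernel)
    rate_mean, _ = mean_sdf(m)
    if mode == "count_fano":
        nv = count_fano(ts, window=matched_window_ms(kernel), step=kernel.dt, c=constants)
        rate_on_grid = np.interp(nv.time_grid, m.time_grid, rate_mean)
    else:
        nv = nv_series(m, constants, mode=mode)
        rate_on_grid = rate_mean
    levels = rate_level_nv(nv, rate_on_grid)
    created += [out / f for f in ("sdf.tsv", "nv.tsv", "rate_levels.tsv", "mean_rate.tsv")]
    svio.write_sdf_matrix(m, out / "sdf.tsv")
    svio.write_nv_table(nv, out / "nv.tsv")
    svio.write_rate_levels(levels, out / "rate_levels.tsv")
    import pandas as pd
    pd.DataFrame({"time_ms": nv.time_grid, "rate": rate_on_grid}).to_csv(
        out / "mean_rate.tsv", sep="\t", index=False, float_format="%.6g")
    _log(out, created, step="analyze", extra={
        "mode": mode, "align_event_ms": ts.align_event, "n_trials": ts.n_trials})
    return {"trialset": ts, "sdf": m, "nv": nv, "levels": levels}


@_cleanup_on_error
def run_report(in_dir: str | Path, plots: bool = False, created=None) -> dict:
    """Summarize an analyzed run: time-mean NV, pre/post-onset NV, levels.

    Returns (and writes as ``report.json``) the time-mean NV, pre- and
    post-onset epoch means when the set is event-aligned, and the
    rate-level table; with ``plots=True`` also saves raster and NV figures.
    """
    import pandas as pd
    d = Path(in_dir)
    nv = svio.read_nv_table(d / "nv.tsv")
    levels = pd.read_csv(d / "rate_levels.tsv", sep="\t")
    log = json.loads((d / "run.json").read_text())
    align = float(log.get("align_event_ms", 0.0))
    report = {
        "mode": nv.mode,
        "n_trials": nv.n_trials,
        "nv_time_mean": nv.time_mean,
        "rate_levels": levels.to_dict(orient="records"),
    }
    if align > 0:  # grid is event-relative: time 0 = target onset
        pre = nv.nv[nv.time_grid < 0]
        post = nv.nv[nv.time_grid >= 0]
        if pre.size and post.size:
            report["nv_pre_onset_mean"] = float(pre.mean())
            report["nv_post_onset_mean"] = float(post.mean())
    (d / "report.json").write_text(json.dumps(report, indent=1))
    created.append(d / "report.json")
    lines = [f"time-mean NV ({nv.mode}, {nv.n_trials} trials): {nv.time_mean:.3f}"]
    if "nv_pre_onset_mean" in report:
        lines.append(f"pre-onset NV mean:  {report['nv_pre_onset_mean']:.3f}")
        lines.append(f"post-onset NV mean: {report['nv_post_onset_mean']:.3f}")
    lines.append("rate-level NV (level, lo, hi, nv_mean, nv_sd, n):")
    for r in report["rate_levels"]:
        lines.append(f"  {r['level']}  [{r['lo']:.2f}, {r['hi']:.2f})  "
                     f"{r['nv_mean']:.3f}  {r['nv_sd']:.3f}  {r['n']}")
    text = "\n".join(lines) + "\n"
    (d / "report.txt").write_text(text)
    created.append(d / "report.txt")
    if plots:
        _plots(d)
    return report


def _plots(d: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ts = svio.read_trialset(d)
    nv = svio.read_nv_table(d / "nv.tsv")
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 6), sharex=False)
    for i, tr in enumerate(ts.trials[:50]):
        ax0.vlines(tr.times, i + 0.5, i + 1.5, lw=0.5, color="k")
    ax0.set(xlabel="time (ms)", ylabel="trial", title="raster (first 50 trials)")
    ax1.plot(nv.time_grid, nv.nv)
    ax1.axhline(1.0, ls="--", c="gray")
    ax1.set(xlabel="time (ms)", ylabel="NV", title=f"normalized variance ({nv.mode})")
    fig.tight_layout()
    fig.savefig(d / "figures.png", dpi=120)
    plt.close(fig)


def _log(out: Path, created: list, step: str, config: RunConfig | None = None,
         extra: dict | None = None) -> None:
    path = out / "run.json"
    log = json.loads(path.read_text()) if path.exists() else {}
    log["step"] = step
    if config is not None:
        log["config_hash"] = config.config_hash()
        log["seed"] = config.seed
    if extra:
        log.update(extra)
    path.write_text(json.dumps(log, indent=1))
    created.append(path)
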