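"""File formats and run configuration.

On-disk format contract
-----------------------
A trial set is a pair of plain-text files in one directory:

``spikes.csv``
    Delimited text, header ``trial,time_ms``, one row per spike; times in ms
    with 6 decimal places, rows grouped by trial with times ascending.
``trialset.json``
    Metadata sidecar with keys ``seed, n_trials, duration_ms, profile,
    noise, offsets, align_event_ms``.

Analysis tables are TSV: the SDF matrix is wide (``time_ms`` plus one column
per trial, kernel parameters in a ``#`` header comment); NV series are tidy
(``time_ms, nv, mode, n_trials``); the rate-level summary has columns
``level, lo, hi, nv_mean, nv_sd, n``.

Run configuration is a YAML file that round-trips losslessly through
:class:`RunConfig`; missing fields are filled from the documented defaults
(100 trials, 1000 ms, 30 ms kernel, k=0.1, eps=eps'=0.01).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rate_model import NoiseSpec, RateProfile
from .sdf import KernelSpec, SDFMatrix
from .spikegen import SpikeTrain, TrialSet
from .variability import NVConstants, NVSeries, RateLevelBins

__all__ = [
    "RunConfig",
    "write_trialset",
    "read_trialset",
    "write_sdf_matrix",
    "read_sdf_matrix",
    "write_nv_table",
    "read_nv_table",
    "write_rate_levels",
]

SPIKES_FILE = "spikes.csv"
META_FILE = "trialset.json"


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """One simulation/analysis run: profile, noise, kernel and NV settings."""

    profile: RateProfile = RateProfile(kind="constant", duration=1000.0, baseline_rate=20.0)
    noise: NoiseSpec = NoiseSpec()
    n_trials: int = 100
    seed: int = 0
    kernel: KernelSpec = KernelSpec()
    constants: NVConstants = NVConstants()
    mode: str = "calibrated"

    def to_dict(self) -> dict:
        p = {"kind": self.profile.kind, "duration_ms": self.profile.duration,
             "baseline_rate": self.profile.baseline_rate}
        if self.profile.kind == "task_epoch":
            p.update(peak_rate=self.profile.peak_rate,
                     target_onset_ms=self.profile.target_onset,
                     rise_time_ms=self.profile.rise_time)
        return {
            "profile": p,
            "noise": {"kind": self.noise.kind, "sigma": self.noise.sigma,
                      "clip_at_zero": self.noise.clip_at_zero},
            "n_trials": self.n_trials,
            "seed": self.seed,
            "kernel": {"sigma_ms": self.kernel.sigma, "dt_ms": self.kernel.dt,
                       "truncation": self.kernel.truncation},
            "nv": {"mode": self.mode, "k": self.constants.k, "eps": self.constants.eps,
                   "eps_prime": self.constants.eps_prime},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        defaults = cls().to_dict()
        merged = {k: {**defaults[k], **d.get(k, {})} if isinstance(defaults[k], dict)
                  else d.get(k, defaults[k]) for k in defaults}
        p = merged["profile"]
        profile = RateProfile(
            kind=p["kind"], duration=float(p["duration_ms"]),
            baseline_rate=float(p["baseline_rate"]),
            peak_rate=None if p.get("peak_rate") is None else float(p["peak_rate"]),
            target_onset=None if p.get("target_onset_ms") is None else float(p["target_onset_ms"]),
            rise_time=None if p.get("rise_time_ms") is None else float(p["rise_time_ms"]),
        )
        n = merged["noise"]
        noise = NoiseSpec(sigma=float(n["sigma"]), kind=n["kind"],
                          clip_at_zero=bool(n["clip_at_zero"]))
        kk = merged["kernel"]
        kernel = KernelSpec(sigma=float(kk["sigma_ms"]), dt=float(kk["dt_ms"]),
                            truncation=float(kk["truncation"]))
        nv = merged["nv"]
        constants = NVConstants(k=float(nv["k"]), eps=float(nv["eps"]),
                                eps_prime=float(nv["eps_prime"]))
        return cls(profile=profile, noise=noise, n_trials=int(merged["n_trials"]),
                   seed=int(merged["seed"]), kernel=kernel, constants=constants,
                   mode=nv["mode"])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Stable short hash of the canonical config, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trial sets

def write_trialset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write ``spikes.csv`` + ``trialset.json`` for an unaligned trial set."""
    if ts.t_start != 0.0:
        raise ValueError("serialize trial sets in the raw trial clock (before alignment)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(i, t) for i, tr in enumerate(ts.trials) for t in tr.times]
    df = pd.DataFrame(rows, columns=["trial", "time_ms"])
    df.to_csv(out / SPIKES_FILE, index=False, float_format="%.6f")
    profile = None
    if ts.profile is not None:
        profile = RunConfig(profile=ts.profile).to_dict()["profile"]
    noise = None
    if ts.noise is not None:
        noise = {"kind": ts.noise.kind, "sigma": ts.noise.sigma,
                 "clip_at_zero": ts.noise.clip_at_zero}
    meta = {
        "seed": ts.seed,
        "n_trials": ts.n_trials,
        "duration_ms": ts.duration,
        "profile": profile,
        "noise": noise,
        "offsets": [float(o) for o in ts.offsets],
        "align_event_ms": ts.align_event,
    }
    (out / META_FILE).write_text(json.dumps(meta, indent=1))
    return out


def read_trialset(in_dir: str | Path) -> TrialSet:
    """Read and validate a trial set written by :func:`write_trialset`.

    Malformed rows are reported with their line number; times outside
    ``[0, duration)``, unsorted times within a trial, and mismatches
    between the spike table and the sidecar are rejected.
    """
    d = Path(in_dir)
    meta = json.loads((d / META_FILE).read_text())
    n_trials = int(meta["n_trials"])
    duration = float(meta["duration_ms"])
    if len(meta["offsets"]) != n_trials:
        raise ValueError(f"{META_FILE}: offsets length != n_trials")
    trials_times: list[list[float]] = [[] for _ in range(n_trials)]
    with open(d / SPIKES_FILE) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["trial", "time_ms"]:
            raise ValueError(f"{SPIKES_FILE} line 1: expected header 'trial,time_ms'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                trial = int(parts[0])
                t = float(parts[1])
            except (ValueError, IndexError):
                raise ValueError(f"{SPIKES_FILE} line {lineno}: malformed row {line!r}")
            if not 0 <= trial < n_trials:
                raise ValueError(f"{SPIKES_FILE} line {lineno}: trial {trial} outside 0..{n_trials - 1}")
            if not 0.0 <= t < duration:
                raise ValueError(
                    f"{SPIKES_FILE} line {lineno}: time {t} ms outside [0, {duration}) ms")
            if trials_times[trial] and t < trials_times[trial][-1]:
                raise ValueError(f"{SPIKES_FILE} line {lineno}: times not sorted within trial {trial}")
            trials_times[trial].append(t)
    profile = None
    if meta.get("profile") is not None:
        profile = RunConfig.from_dict({"profile": meta["profile"]}).profile
    noise = None
    if meta.get("noise") is not None:
        nd = meta["noise"]
        noise = NoiseSpec(sigma=float(nd["sigma"]), kind=nd["kind"],
                          clip_at_zero=bool(nd["clip_at_zero"]))
    trials = tuple(SpikeTrain(times=np.array(t), duration=duration) for t in trials_times)
    return TrialSet(trials=trials, profile=profile, noise=noise,
                    offsets=np.array(meta["offsets"]),
                    seed=meta.get("seed"), align_event=float(meta.get("align_event_ms", 0.0)))


# ---------------------------------------------------------------------------
# analysis tables

def write_sdf_matrix(m: SDFMatrix, path: str | Path) -> None:
    """Wide TSV: time_ms + one column per trial; kernel params in a comment."""
    path = Path(path)
    header = (f"# sdf spikes/s; kernel sigma_ms={m.kernel.sigma} dt_ms={m.kernel.dt} "
              f"truncation={m.kernel.truncation}\n")
    df = pd.DataFrame(m.values.T, columns=[f"trial_{i}" for i in range(m.n_trials)])
    df.insert(0, "time_ms", m.time_grid)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_sdf_matrix(path: str | Path) -> SDFMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sdf"):
            raise ValueError("missing SDF header comment")
        params = dict(p.split("=") for p in header.split(";")[1].split() if "=" in p)
        kernel = KernelSpec(sigma=float(params["sigma_ms"]), dt=float(params["dt_ms"]),
                            truncation=float(params["truncation"]))
        df = pd.read_csv(fh, sep="\t")
    grid = df.pop("time_ms").to_numpy()
    return SDFMatrix(values=df.to_numpy().T, time_grid=grid, kernel=kernel)


def write_nv_table(s: NVSeries, path: str | Path) -> None:
    """Tidy TSV: time_ms, nv, mode, n_trials."""
    df = pd.DataFrame({"time_ms": s.time_grid, "nv": s.nv,
                       "mode": s.mode, "n_trials": s.n_trials})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_nv_table(path: str | Path, constants: NVConstants = NVConstants()) -> NVSeries:
    df = pd.read_csv(path, sep="\t")
    return NVSeries(time_grid=df["time_ms"].to_numpy(), nv=df["nv"].to_numpy(),
                    mode=str(df["mode"].iloc[0]), constants=constants,
                    n_trials=int(df["n_trials"].iloc[0]))


def write_rate_levels(b: RateLevelBins, path: str | Path) -> None:
    df = pd.DataFrame({"level": np.arange(len(b.lo)), "lo": b.lo, "hi": b.hi,
                       "nv_mean": b.nv_mean, "nv_sd": b.nv_sd, "n": b.n})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
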