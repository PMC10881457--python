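"""Experiment presets, trials, and parameter-sweep driver.

A *trial* is one full pipeline pass: sample both populations' weights
from the trial seed, generate a seeded training stream, co-train the
readouts by mutual FORCE learning, freeze the weights, run both
populations on a fresh test stream, and score the test readouts with
the TOPA metrics.

A *sweep* runs a Cartesian grid of parameter settings, each over a list
of seeds, and aggregates trial- and window-level records into tidy
tables.  Eight presets encode the simulation experiments:

1. time constants of the two populations varied independently (2-30 ms)
2. self-feedback gain h varied (0.1-2.2)
3. common connection probability of recurrent/feedback/input matrices
   varied (0.1-1.0)
4. recurrent gain g varied (0.25-2.25) at N=600, sparse connectivity
5. teaching coefficients kappa_1, kappa_2 varied in [-1, 1],
   unrectified teaching signals
6. chunk length increased from 4 to 6 characters, time constants varied
7. early-recognition combination (g=0.5, h=0.4), time constants varied
8. FORCE learning rate alpha (20-160) x training time (1-10 s)

Seed policy: within a sweep, the trial seed depends only on the
replicate index (not on the grid point), and the test stream comes from
a held-out seed shared across grid points, so surfaces are comparable
across the grid with matched realizations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .chunk_stream import ChunkProtocol, generate_input
from .learning import TeachingConfig, TrainingConfig, train_pair
from .metrics import (
    TOPAResult,
    aggregate_over_seeds,
    count_modes,
    score_trace,
    topa_histogram,
)
from .network import ReservoirParams, init_weights, run_population

logger = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "TrialResult",
    "ExperimentPreset",
    "SweepResult",
    "preset",
    "run_trial",
    "run_sweep",
    "apply_setting",
    "config_from_dict",
    "config_to_dict",
]

#: Base of the held-out test-stream seeds (replicate j tests on
#: HELD_OUT_TEST_SEED + j at every grid point).
HELD_OUT_TEST_SEED = 1_000_003

_BASELINE_TAUS = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0)


@dataclass(frozen=True)
class TrialConfig:
    """Complete configuration of one trial."""

    protocol: ChunkProtocol = field(default_factory=ChunkProtocol)
    population_1: ReservoirParams = field(default_factory=ReservoirParams)
    population_2: ReservoirParams = field(default_factory=ReservoirParams)
    teaching: TeachingConfig = field(default_factory=TeachingConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)


@dataclass
class TrialResult:
    """Post-training metrics of one trial, both populations."""

    seed: int
    test_seed: int
    config: TrialConfig
    topa_1: TOPAResult
    topa_2: TOPAResult
    windows: tuple[tuple[float, float], ...]
    z_test_1: np.ndarray | None = None
    z_test_2: np.ndarray | None = None

    @property
    def populations(self) -> tuple[TOPAResult, TOPAResult]:
        return (self.topa_1, self.topa_2)

    def to_frame(self) -> pd.DataFrame:
        """Tidy window-level rows: one per (population, window)."""
        rows = []
        for pop, res in enumerate(self.populations, start=1):
            for j in range(res.n_windows):
                rows.append(
                    dict(
                        seed=self.seed,
                        population=pop,
                        window=j,
                        offset_ms=res.offsets[j],
                        peak=res.peaks[j],
                        zscore=res.zscores[j],
                        min_peak=res.min_peaks[j],
                        min_zscore=res.min_zscores[j],
                    )
                )
        return pd.DataFrame(rows)


def run_trial(
    config: TrialConfig,
    seed: int,
    test_seed: int | None = None,
    record_traces: bool = False,
) -> TrialResult:
    """Run one full train-freeze-test pipeline pass.

    ``seed`` drives the weight sampling, the training stream and all
    process noise through independent sub-streams.  ``test_seed`` fixes
    the test stream; when ``None`` it is derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    (
        s_weights_1,
        s_weights_2,
        s_train_stream,
        s_train_dyn,
        s_test_dyn_1,
        s_test_dyn_2,
        s_test_stream,
    ) = ss.spawn(7)

    protocol = config.protocol
    dt = config.population_1.dt
    train_protocol = replace(
        protocol, total_duration=float(config.training.t_train_ms or 0.0)
    )
    test_protocol = replace(protocol, total_duration=config.training.t_test_ms)

    w1 = init_weights(config.population_1, protocol.alphabet_size, s_weights_1)
    w2 = init_weights(config.population_2, protocol.alphabet_size, s_weights_2)

    if train_protocol.total_duration >= train_protocol.char_duration:
        train_input = generate_input(train_protocol, s_train_stream, dt)
        trained = train_pair(
            w1,
            w2,
            config.population_1,
            config.population_2,
            config.teaching,
            config.training,
            train_input,
            s_train_dyn,
        )
        w1, w2 = trained.weights_1, trained.weights_2

    if test_seed is None:
        test_stream_seed: Any = s_test_stream
        test_seed_out = -1
    else:
        test_stream_seed = int(test_seed)
        test_seed_out = int(test_seed)
    test_input = generate_input(test_protocol, test_stream_seed, dt)

    trace_1 = run_population(w1, config.population_1, test_input, seed=s_test_dyn_1)
    trace_2 = run_population(w2, config.population_2, test_input, seed=s_test_dyn_2)

    wl = protocol.window_length
    res_1 = score_trace(trace_1.z, test_input.windows, dt, wl)
    res_2 = score_trace(trace_2.z, test_input.windows, dt, wl)
    return TrialResult(
        seed=seed,
        test_seed=test_seed_out,
        config=config,
        topa_1=res_1,
        topa_2=res_2,
        windows=test_input.windows,
        z_test_1=trace_1.z if record_traces else None,
        z_test_2=trace_2.z if record_traces else None,
    )


# ---------------------------------------------------------------------------
# Configuration plumbing: named settings, dict/YAML round-trip, presets
# ---------------------------------------------------------------------------

def _set_populations(config: TrialConfig, both: bool = True, **kw) -> TrialConfig:
    return replace(
        config,
        population_1=replace(config.population_1, **kw),
        population_2=replace(config.population_2, **kw) if both else config.population_2,
    )


def apply_setting(config: TrialConfig, key: str, value: Any) -> TrialConfig:
    """Apply one named parameter setting and return a new config.

    Recognized keys: ``tau`` (both populations), ``tau_1``, ``tau_2``,
    ``feedback_gain`` (h), ``recurrent_gain`` (g), ``p3`` (common
    connection probability: recurrent + feedback + input), ``p_recurrent``,
    ``n_neurons``, ``noise_std``, ``kappa_1``, ``kappa_2``, ``kappa``
    (both), ``beta``, ``rectify``, ``alpha``, ``t_train_s``, ``t_test_s``,
    ``chunk_length``, ``chunk_rate``, ``alphabet_size``, ``char_duration``.
    """
    if key == "tau":
        return _set_populations(config, tau=float(value))
    if key == "tau_1":
        return replace(config, population_1=replace(config.population_1, tau=float(value)))
    if key == "tau_2":
        return replace(config, population_2=replace(config.population_2, tau=float(value)))
    if key in ("feedback_gain", "recurrent_gain", "noise_std", "p_recurrent"):
        return _set_populations(config, **{key: float(value)})
    if key == "n_neurons":
        # keep the readout width (n <= N); clamp when shrinking
        n = int(value)
        return replace(
            config,
            population_1=replace(
                config.population_1,
                n_neurons=n,
                n_readout=min(config.population_1.n_readout, n),
            ),
            population_2=replace(
                config.population_2,
                n_neurons=n,
                n_readout=min(config.population_2.n_readout, n),
            ),
        )
    if key == "p3":
        # common connection probability across all three weight matrices
        return _set_populations(config, p_recurrent=float(value), p3=float(value))
    if key == "p3_only":
        return _set_populations(config, p3=float(value))
    if key in ("kappa_1", "kappa_2", "beta"):
        return replace(config, teaching=replace(config.teaching, **{key: float(value)}))
    if key == "kappa":
        return replace(
            config,
            teaching=replace(
                config.teaching, kappa_1=float(value), kappa_2=float(value)
            ),
        )
    if key == "rectify":
        flag = value if isinstance(value, bool) else str(value).lower() in ("1", "true", "yes")
        return replace(config, teaching=replace(config.teaching, rectify=flag))
    if key == "alpha":
        return replace(config, training=replace(config.training, alpha=float(value)))
    if key == "t_train_s":
        return replace(
            config, training=replace(config.training, t_train_ms=float(value) * 1000.0)
        )
    if key == "t_test_s":
        return replace(
            config, training=replace(config.training, t_test_ms=float(value) * 1000.0)
        )
    if key == "chunk_length":
        return replace(
            config, protocol=replace(config.protocol, chunk=tuple(range(int(value))))
        )
    if key in ("chunk_rate", "char_duration"):
        return replace(config, protocol=replace(config.protocol, **{key: float(value)}))
    if key == "alphabet_size":
        return replace(config, protocol=replace(config.protocol, alphabet_size=int(value)))
    raise KeyError(f"unknown setting: {key!r}")


_CONFIG_SECTIONS = {
    "input": ("protocol", ChunkProtocol),
    "population_1": ("population_1", ReservoirParams),
    "population_2": ("population_2", ReservoirParams),
    "teaching": ("teaching", TeachingConfig),
    "training": ("training", TrainingConfig),
}


def config_from_dict(data: Mapping[str, Any]) -> TrialConfig:
    """Build a trial configuration from nested config-file sections.

    Sections: ``input``, ``population`` (applied to both) and/or
    ``population_1``/``population_2``, ``teaching``, ``training``.
    Unknown sections or fields raise.
    """
    config = TrialConfig()
    data = dict(data)
    shared_pop = data.pop("population", None)
    if shared_pop is not None:
        config = replace(
            config,
            population_1=ReservoirParams(**shared_pop),
            population_2=ReservoirParams(**shared_pop),
        )
    for section, payload in data.items():
        if section not in _CONFIG_SECTIONS:
            raise KeyError(f"unknown config section: {section!r}")
        attr, cls = _CONFIG_SECTIONS[section]
        if section == "input" and "chunk" in payload:
            payload = dict(payload, chunk=tuple(payload["chunk"]))
        config = replace(config, **{attr: cls(**payload)})
    return config


def config_to_dict(config: TrialConfig) -> dict[str, Any]:
    """Serialize a trial configuration to plain nested dicts."""
    out: dict[str, Any] = {}
    for section, (attr, _) in _CONFIG_SECTIONS.items():
        obj = getattr(config, attr)
        d = dataclasses.asdict(obj)
        if "chunk" in d:
            d["chunk"] = list(d["chunk"])
        out[section] = d
    return out


@dataclass(frozen=True)
class ExperimentPreset:
    """A named parameter grid over a fixed baseline configuration."""

    id: int
    name: str
    grid: tuple[tuple[str, tuple], ...]  # ordered (key, values) axes
    fixed: TrialConfig
    seeds: tuple[int, ...] = tuple(range(10))

    @property
    def grid_axes(self) -> dict[str, tuple]:
        return dict(self.grid)

    def points(self):
        """Iterate over grid points as {key: value} dicts."""
        keys = [k for k, _ in self.grid]
        for values in itertools.product(*(v for _, v in self.grid)):
            yield dict(zip(keys, values))

    def config_at(self, point: Mapping[str, Any]) -> TrialConfig:
        config = self.fixed
        for key, value in point.items():
            config = apply_setting(config, key, value)
        return config


def _frange(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


def preset(experiment_id: int, seeds: Sequence[int] | None = None) -> ExperimentPreset:
    """Return the configuration of one of the eight simulation experiments.

    Baseline (shared unless overridden): N=300, n=300, sigma=0.3,
    beta=3, tau=10 ms, h=1, g=1.5, p=p3=1, kappa=1, chunk length 4,
    alpha=100, 10 s training and test streams, 10 seeds.
    """
    base = TrialConfig()
    taus = _BASELINE_TAUS
    if experiment_id == 1:
        grid = (("tau_1", taus), ("tau_2", taus))
        fixed = base
        name = "time-constants"
    elif experiment_id == 2:
        grid = (("feedback_gain", (0.1, 0.2, 0.6, 1.0, 1.4, 1.8, 2.2)),)
        fixed = base
        name = "self-feedback-gain"
    elif experiment_id == 3:
        grid = (("p3", _frange(0.1, 1.0, 0.1)),)
        fixed = base
        name = "connection-probability"
    elif experiment_id == 4:
        grid = (("recurrent_gain", _frange(0.25, 2.25, 0.25)),)
        fixed = apply_setting(
            _set_populations(base, n_neurons=600), "p3", 0.3
        )
        name = "recurrent-gain"
    elif experiment_id == 5:
        kappas = (-1.0, -0.5, 0.0, 0.5, 1.0)
        grid = (("kappa_1", kappas), ("kappa_2", kappas))
        fixed = apply_setting(base, "rectify", False)
        fixed = replace(
            fixed,
            population_1=replace(fixed.population_1, p_recurrent=0.25),
            population_2=replace(fixed.population_2, p_recurrent=0.25),
        )
        name = "teaching-coefficient"
    elif experiment_id == 6:
        grid = (("tau_1", taus), ("tau_2", taus))
        fixed = apply_setting(base, "chunk_length", 6)
        name = "chunk-length-6"
    elif experiment_id == 7:
        grid = (("tau_1", taus), ("tau_2", taus))
        fixed = _set_populations(base, recurrent_gain=0.5, feedback_gain=0.4)
        name = "combined-early-recognition"
    elif experiment_id == 8:
        grid = (
            ("alpha", _frange(20.0, 160.0, 20.0)),
            ("t_train_s", _frange(1.0, 10.0, 1.0)),
        )
        fixed = base
        name = "learning-rate-and-training-time"
    else:
        raise ValueError(f"experiment id must be 1..8, got {experiment_id}")
    seed_tuple = tuple(int(s) for s in (seeds if seeds is not None else range(10)))
    return ExperimentPreset(
        id=experiment_id, name=name, grid=grid, fixed=fixed, seeds=seed_tuple
    )


# ---------------------------------------------------------------------------
# Sweep driver
# ---------------------------------------------------------------------------

def _point_id(point: Mapping[str, Any]) -> str:
    return "|".join(f"{k}={point[k]:g}" for k in point)


@dataclass
class SweepResult:
    """Aggregated outcome of a parameter sweep.

    ``trials``: one row per (grid point, seed, population) with mean
    TOPA and mean peak z-score.  ``windows``: one row per scored chunk
    window.  ``failures``: recorded trial errors (the sweep continues
    past them).
    """

    preset_id: int
    trials: pd.DataFrame
    windows: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    def summary(self, across_populations: bool = True) -> pd.DataFrame:
        """Per-grid-point means over seeds (and optionally populations)."""
        keys = [c for c in self.trials.columns if c.startswith("grid:")]
        group = keys if across_populations else keys + ["population"]
        cols = ["mean_topa", "mean_zscore", "peak_zscore", "peak_topa"]
        return (
            self.trials.groupby(group, as_index=False)[cols]
            .mean()
            .rename(columns={c: c.removeprefix("grid:") for c in keys})
        )

    def pooled_offsets(self, point: Mapping[str, Any] | None = None) -> np.ndarray:
        """Concatenated per-window offsets (both populations, all seeds)."""
        df = self.windows
        if point is not None:
            for k, v in point.items():
                df = df[np.isclose(df[f"grid:{k}"], v)]
        return df["offset_ms"].to_numpy()


def run_sweep(
    sweep: ExperimentPreset,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the full grid x seeds of a preset, aggregating incrementally.

    With ``out_dir`` set, trial- and window-level tables are appended to
    CSV files after every grid point, and grid points already present in
    an existing ``trials.csv`` are skipped, making long sweeps
    restartable.  Failed trials are recorded and skipped.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    done: set[tuple[str, int]] = set()
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        trials_csv = out_path / "trials.csv"
        if trials_csv.exists():
            prev = pd.read_csv(trials_csv)
            done = set(zip(prev["point_id"], prev["seed"]))
            logger.info("resuming sweep: %d trial rows already present", len(prev))

    trial_rows: list[dict] = []
    window_frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    for point in sweep.points():
        pid = _point_id(point)
        config = sweep.config_at(point)
        point_trials: list[dict] = []
        point_windows: list[pd.DataFrame] = []
        for j, seed in enumerate(sweep.seeds):
            if (pid, seed) in done:
                continue
            try:
                result = run_trial(config, seed, test_seed=HELD_OUT_TEST_SEED + j)
            except Exception as exc:  # record and continue
                logger.warning("trial failed at %s seed %d: %s", pid, seed, exc)
                failures.append(dict(point_id=pid, seed=seed, error=str(exc)))
                continue
            for pop, res in enumerate(result.populations, start=1):
                row = {f"grid:{k}": v for k, v in point.items()}
                row.update(
                    point_id=pid,
                    seed=seed,
                    population=pop,
                    n_windows=res.n_windows,
                    mean_topa=res.mean_offset,
                    mean_zscore=res.mean_zscore,
                    peak_zscore=res.global_zscore,
                    peak_topa=res.global_offset,
                    min_peak_zscore=res.global_min_zscore,
                    mean_min_zscore=float(np.nanmean(res.min_zscores))
                    if res.n_windows
                    else float("nan"),
                )
                point_trials.append(row)
            wf = result.to_frame()
            if not wf.empty:
                for k, v in point.items():
                    wf[f"grid:{k}"] = v
                wf["point_id"] = pid
                point_windows.append(wf)
        if progress and point_trials:
            logger.info("sweep %d: finished %s", sweep.id, pid)
        trial_rows.extend(point_trials)
        window_frames.extend(point_windows)
        if out_path is not None and point_trials:
            _append_csv(out_path / "trials.csv", pd.DataFrame(point_trials))
            if point_windows:
                _append_csv(out_path / "windows.csv", pd.concat(point_windows))

    trials = pd.DataFrame(trial_rows)
    windows = (
        pd.concat(window_frames, ignore_index=True)
        if window_frames
        else pd.DataFrame()
    )
    if out_path is not None:
        with open(out_path / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=2)
    return SweepResult(
        preset_id=sweep.id, trials=trials, windows=windows, failures=failures
    )


def _append_csv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, mode="a", header=not path.exists(), index=False)


def run_hash(config: TrialConfig, seeds: Sequence[int]) -> str:
    """Short content hash identifying a run configuration."""
    payload = json.dumps(
        {"config": config_to_dict(config), "seeds": list(seeds)}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
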