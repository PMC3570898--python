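"""Experiment harness: capacity arithmetic, size/noise sweeps, capacity tests.

Every sweep follows the same protocol: for each configuration and each of
``n_runs`` seeded runs, generate the pattern set, train a fresh network (one
programming pass, or ``epochs`` teacher-forced adaptation presentations),
recall every pattern once from its first four spikes, and score each recall
against the strict success threshold.  Results come back as tidy DataFrames
(one row per run, and one row per pattern) plus mean/std summaries where the
standard deviation is taken over runs, not patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Network, ParameterError, SimParams, create_network
from .patterns import (
    Pattern,
    RecallReport,
    check_recall,
    generate_noise,
    generate_pattern_sequence,
)
from .plasticity import AdaptationConfig, program_patterns, train_adaptation

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "capacity",
    "derive_run_seeds",
    "run_recall_trial",
    "run_configuration",
    "sweep_network_size",
    "sweep_noise",
    "spike_recall_distribution",
    "full_capacity_test",
]

#: recall trials abort (and score as failures) past this many emitted spikes
#: per pattern spike — the guard against the all-neurons-fire state
RUNAWAY_FACTOR = 50


def capacity(total_modules: int, pattern_len_spikes: int) -> int:
    """Maximum number of patterns storable without sharing connections.

    Each pattern of L spikes consumes L axon modules (one per spike), so the
    capacity is ``floor(total_modules / L)``.
    """
    if pattern_len_spikes < 1:
        raise ParameterError("pattern length must be >= 1 spike")
    if total_modules < 0:
        raise ParameterError("module count must be >= 0")
    return total_modules // pattern_len_spikes


def derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Expand a master seed into per-run seeds via a splittable scheme."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_runs)]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings for the sweep experiments."""

    mode: str = "programming"  # or "adaptation"
    neuron_sizes: tuple[int, ...] = (256, 512, 1024, 2048, 4096)
    n_axon_arrays: int = 1
    modules_per_array: int = 4096
    patterns_per_run: int = 82
    intervals_per_pattern: int = 50
    n_runs: int = 10
    master_seed: int = 42
    noise_rate_hz: float = 0.0
    success_threshold: float = 0.70
    cue_len: int = 4
    epochs: int = 5
    adaptation_coefficient: float = 0.5
    adaptation_strategy: str = "proportional"

    def __post_init__(self) -> None:
        if self.mode not in ("programming", "adaptation"):
            raise ParameterError(f"unknown training mode {self.mode!r}")
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")

    @property
    def run_seeds(self) -> list[int]:
        return derive_run_seeds(self.master_seed, self.n_runs)


@dataclass
class SweepResult:
    """Tidy per-run and per-pattern results of a sweep."""

    runs: pd.DataFrame  # one row per (configuration, run)
    patterns: pd.DataFrame  # one row per (configuration, run, pattern)
    group_cols: list[str] = field(default_factory=lambda: ["n_neurons", "mode"])

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of success % across runs."""
        g = self.runs.groupby(self.group_cols, as_index=False)["success_pct"]
        out = g.mean().rename(columns={"success_pct": "mean_success_pct"})
        out["std_success_pct"] = g.std(ddof=1)["success_pct"].fillna(0.0).to_numpy()
        return out


def _default_duration(pattern: Pattern, params: SimParams) -> int:
    # trained duration plus ten delay ceilings: residual activity dies out
    return pattern.duration + 10 * params.delay_max_ticks


def run_recall_trial(
    net: Network,
    pattern: Pattern,
    noise_rate_hz: float = 0.0,
    seed: int = 0,
    success_threshold: float = 0.70,
    cue_len: int = 4,
    duration_ticks: int | None = None,
) -> RecallReport:
    """Cue the network with the pattern's first spikes and score the recall.

    The cue (and Poisson noise, if any) is injected on the post-synaptic bus
    at the trained relative ticks; the network then runs freely and the spikes
    it emits are checked against the full reference pattern.  A runaway trial
    (emitted spikes exceeding ``RUNAWAY_FACTOR`` per pattern spike) aborts and
    scores as a failed recall with zero coincident spikes.
    """
    rng = np.random.default_rng(seed)
    noise_seed = int(rng.integers(0, 2**31))
    checker_seed = int(rng.integers(0, 2**31))
    if duration_ticks is None:
        duration_ticks = _default_duration(pattern, net.params)
    net.reset_dynamics()
    net.inject(pattern.events[:cue_len])
    if noise_rate_hz > 0:
        net.inject(
            generate_noise(
                noise_rate_hz,
                duration_ticks,
                net.params.n_neurons,
                noise_seed,
                net.params.tick_us,
            )
        )
    recalled = net.run(duration_ticks, max_spikes=RUNAWAY_FACTOR * len(pattern))
    if net.runaway:
        return RecallReport(
            pattern_id=pattern.pattern_id,
            n_reference_spikes=len(pattern),
            n_checked=len(pattern) - cue_len,
            n_coincident=0,
            success=False,
            runaway=True,
        )
    return check_recall(pattern, cue_len, recalled, success_threshold, checker_seed)


def _make_patterns(
    rng: np.random.Generator, n_patterns: int, n_neurons: int, n_intervals: int
) -> list[Pattern]:
    # one seed pair per run: the free-running LFSRs generate the whole set.
    # the pair is drawn before anything else so that, for a fixed run seed,
    # the interval sequences are identical across network sizes
    seed_neuron = int(rng.integers(1, 2**20))
    seed_interval = int(rng.integers(1, 2**20))
    return generate_pattern_sequence(
        seed_neuron, seed_interval, n_neurons, n_intervals, n_patterns
    )


def _train(net: Network, patterns: list[Pattern], cfg: ExperimentConfig, run_seed: int):
    if cfg.mode == "programming":
        return program_patterns(net, patterns)
    return train_adaptation(
        net,
        patterns,
        AdaptationConfig(
            strategy=cfg.adaptation_strategy,
            coefficient=cfg.adaptation_coefficient,
            epochs=cfg.epochs,
            init_delay_range=(1, net.params.delay_max_ticks),
            rng_seed=run_seed,
        ),
    )


def run_configuration(
    cfg: ExperimentConfig,
    n_neurons: int,
    run_seed: int,
    noise_rates: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """One seeded run of one configuration; returns per-pattern rows.

    If ``noise_rates`` is given, the trained network is reused to recall the
    whole pattern set once per rate (training itself is always noiseless).
    """
    rng = np.random.default_rng(run_seed)
    patterns = _make_patterns(
        rng, cfg.patterns_per_run, n_neurons, cfg.intervals_per_pattern
    )
    params = SimParams(
        n_neurons=n_neurons,
        n_axon_arrays=cfg.n_axon_arrays,
        modules_per_array=cfg.modules_per_array,
    )
    net = create_network(params)
    _train(net, patterns, cfg, run_seed)
    rates = noise_rates if noise_rates is not None else (cfg.noise_rate_hz,)
    rows = []
    for rate in rates:
        for p in patterns:
            trial_seed = int(rng.integers(0, 2**31))
            rep = run_recall_trial(
                net,
                p,
                noise_rate_hz=rate,
                seed=trial_seed,
                success_threshold=cfg.success_threshold,
                cue_len=cfg.cue_len,
            )
            rows.append(
                {
                    "n_neurons": n_neurons,
                    "mode": cfg.mode,
                    "noise_rate_hz": rate,
                    "run_seed": run_seed,
                    "pattern_id": p.pattern_id,
                    "n_checked": rep.n_checked,
                    "n_coincident": rep.n_coincident,
                    "spike_fraction": rep.spike_fraction,
                    "success": rep.success,
                    "runaway": rep.runaway,
                }
            )
    return pd.DataFrame(rows)


def _aggregate(pattern_df: pd.DataFrame, group_cols: list[str]) -> SweepResult:
    runs = (
        pattern_df.groupby(group_cols + ["run_seed"], as_index=False)
        .agg(success_pct=("success", lambda s: 100.0 * s.mean()),
             n_runaway=("runaway", "sum"))
    )
    return SweepResult(runs=runs, patterns=pattern_df, group_cols=group_cols)


def sweep_network_size(cfg: ExperimentConfig) -> SweepResult:
    """Success percentage vs. neuron-array size (Fig. 11-style sweep)."""
    frames = []
    for size in cfg.neuron_sizes:
        for seed in cfg.run_seeds:
            frames.append(run_configuration(cfg, size, seed))
    return _aggregate(pd.concat(frames, ignore_index=True), ["n_neurons", "mode"])


def sweep_noise(
    cfg: ExperimentConfig,
    noise_rates: tuple[float, ...] = (2, 4, 8, 16, 32, 64, 128),
    n_neurons: int = 4096,
) -> SweepResult:
    """Success percentage vs. Poisson noise rate (Fig. 13-style sweep).

    Noise is present only during recall; the first (and only) training pass
    is noiseless.  The trained network of each run is reused for all rates.
    """
    frames = [
        run_configuration(cfg, n_neurons, seed, noise_rates=tuple(noise_rates))
        for seed in cfg.run_seeds
    ]
    return _aggregate(
        pd.concat(frames, ignore_index=True), ["n_neurons", "mode", "noise_rate_hz"]
    )


def spike_recall_distribution(cfg: ExperimentConfig) -> pd.DataFrame:
    """Per-pattern spike-recall fractions for each size (Fig. 12-style)."""
    return sweep_network_size(cfg).patterns


def full_capacity_test(
    cfg: ExperimentConfig | None = None,
    scale: float = 0.1,
    pattern_lengths: tuple[int, ...] = (21, 51),
    modes: tuple[str, ...] = ("programming", "adaptation"),
    n_neurons: int = 4096,
    full_arrays: int = 70,
) -> SweepResult:
    """Load the network to capacity and recall every stored pattern.

    At ``scale`` 1 this is the 70-array, 4096-neuron configuration storing
    5621 patterns of 51 spikes (or 13653 of 21); smaller scales shrink the
    axon-array count and hence the pattern count proportionally for
    desk-scale runs.  The stored pattern count is the floor capacity, so all
    patterns are fully stored.
    """
    if cfg is None:
        cfg = ExperimentConfig()
    arrays = max(1, round(full_arrays * scale))
    frames = []
    for mode in modes:
        for length in pattern_lengths:
            n_patterns = capacity(arrays * cfg.modules_per_array, length)
            sub = replace(
                cfg,
                mode=mode,
                n_axon_arrays=arrays,
                patterns_per_run=n_patterns,
                intervals_per_pattern=length - 1,
            )
            for seed in sub.run_seeds:
                df = run_configuration(sub, n_neurons, seed)
                df["pattern_len"] = length
                frames.append(df)
    return _aggregate(
        pd.concat(frames, ignore_index=True), ["mode", "pattern_len"]
    )
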