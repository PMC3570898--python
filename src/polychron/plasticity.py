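"""Learning procedures that set the axonal delays.

Two training modes configure the write-once module table:

* **Delay programming** — each spike of a training pattern consumes the next
  unconfigured axon module: the module latches the spike's address as its
  input, the next four pattern spikes as its outputs, and the corresponding
  inter-spike spans as its four delays.  One pass stores a pattern exactly.

* **Delay adaptation** — the first presentation allocates addresses the same
  way but initializes the delays randomly; on every further presentation each
  delay is nudged toward the observed timing difference between the module's
  ramp start (its input spike) and its output neuron's firing.  During
  training the full pattern is injected externally, so the observed firing
  times are the trained spike times (teacher forcing).  Three step-size
  strategies exist: ``one_step`` (jump straight to the measured value, which
  makes adaptation equivalent to programming), ``single_count`` (move one tick
  per presentation) and ``proportional`` (move a fixed fraction, 0.5 by
  default, of the remaining difference — geometric convergence).

Spans longer than the delay ceiling saturate: programming clamps them to
``delay_max_ticks`` (a silent path, as the 9-bit ramp comparator can never
pass its ceiling) and adaptation converges toward the same ceiling because
the saturated ramp reads ``delay_max_ticks`` when the output neuron fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import UNSET, Network, ParameterError
from .patterns import Pattern

__all__ = [
    "STRATEGIES",
    "AdaptationConfig",
    "TrainingReport",
    "adapt_delay",
    "program_pattern",
    "program_patterns",
    "train_adaptation",
    "enable_recall_adaptation",
]

STRATEGIES = ("one_step", "single_count", "proportional")


@dataclass(frozen=True)
class AdaptationConfig:
    """Settings for delay-adaptation training.

    ``epochs`` counts presentations of each pattern, including the first,
    configuring one; ``coefficient`` is the proportional step fraction;
    ``init_delay_range`` bounds (inclusive) the random initial delays.
    """

    strategy: str = "proportional"
    coefficient: float = 0.5
    epochs: int = 5
    init_delay_range: tuple[int, int] = (1, 511)
    rng_seed: int = 0
    updates: str = "cyclic"  # or "single"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if not (0.0 < self.coefficient <= 1.0):
            raise ParameterError("coefficient must be in (0, 1]")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        lo, hi = self.init_delay_range
        if not (1 <= lo <= hi):
            raise ParameterError("init_delay_range must satisfy 1 <= low <= high")
        if self.updates not in ("cyclic", "single"):
            raise ParameterError("updates must be 'cyclic' or 'single'")


@dataclass
class TrainingReport:
    """Bookkeeping returned by the training procedures."""

    modules_consumed: int = 0
    patterns_fully_stored: int = 0
    patterns_partially_stored: int = 0
    spans_clamped: int = 0
    epoch_mean_abs_error: list[float] = field(default_factory=list)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (integer delay registers)."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def adapt_delay(
    strategy: str,
    programmed_delay: int,
    ramp_at_fire: int,
    coefficient: float = 0.5,
    delay_max_ticks: int = 511,
) -> int:
    """One adaptation update of a single delay path.

    ``ramp_at_fire`` is the module's ramp value when the path's output neuron
    fired (the measured pre/post timing difference relative to ramp start).
    """
    if strategy == "one_step":
        new = ramp_at_fire
    elif strategy == "single_count":
        diff = ramp_at_fire - programmed_delay
        new = programmed_delay + (1 if diff > 0 else -1 if diff < 0 else 0)
    elif strategy == "proportional":
        correction = _round_half_away(coefficient * (ramp_at_fire - programmed_delay))
        new = programmed_delay + correction
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    return max(0, min(delay_max_ticks, new))


def _allocate(net: Network, pattern: Pattern) -> tuple[list[int], TrainingReport]:
    """Consume one module per pattern spike; configure addresses.

    Returns the consumed module indices (one per configured spike) and a
    report.  Delays are NOT written here; callers fill them in.
    """
    report = TrainingReport()
    n_modules = net.params.n_modules
    consumed: list[int] = []
    events = pattern.events
    for k in range(len(events)):
        if net.programming_index >= n_modules:
            break
        m = net.programming_index
        net.input_addrs[m] = events[k].address
        for j in range(4):
            if k + 1 + j < len(events):
                net.out_addrs[m][j] = events[k + 1 + j].address
        net.programming_index += 1
        consumed.append(m)
    report.modules_consumed = len(consumed)
    if len(consumed) == len(events) and len(events) > 0:
        report.patterns_fully_stored = 1
    elif consumed:
        report.patterns_partially_stored = 1
    net.invalidate_routing()
    return consumed, report


def _span(pattern: Pattern, k: int, j: int) -> int | None:
    """Trained inter-spike span covered by path j of the module of spike k."""
    if k + 1 + j >= len(pattern.events):
        return None
    return pattern.events[k + 1 + j].tick - pattern.events[k].tick


def program_pattern(net: Network, pattern: Pattern) -> TrainingReport:
    """Store one pattern by write-once delay programming.

    The module consumed by spike *k* takes the pattern's spike *k* address as
    input, spikes *k+1..k+4* as outputs, and the corresponding tick spans as
    delays.  Spans beyond the delay ceiling are clamped to it (silent paths)
    and counted in the report.  Once all modules are consumed, further spikes
    configure nothing.
    """
    if len(pattern) == 0:
        return TrainingReport()
    consumed, report = _allocate(net, pattern)
    dmax = net.params.delay_max_ticks
    for idx, m in enumerate(consumed):
        for j in range(4):
            s = _span(pattern, idx, j)
            if s is None:
                continue
            if s > dmax:
                report.spans_clamped += 1
                s = dmax
            net.delays[m][j] = s
    net.invalidate_routing()
    return report


def program_patterns(net: Network, patterns: list[Pattern]) -> TrainingReport:
    """Program a sequence of patterns; aggregates the per-pattern reports."""
    total = TrainingReport()
    for p in patterns:
        r = program_pattern(net, p)
        total.modules_consumed += r.modules_consumed
        total.patterns_fully_stored += r.patterns_fully_stored
        total.patterns_partially_stored += r.patterns_partially_stored
        total.spans_clamped += r.spans_clamped
    return total


def _converged_update(
    config: AdaptationConfig, delay: int, target: int, dmax: int
) -> int:
    """Apply the adaptor's update(s) for one measurement.

    With ``updates='single'`` exactly one :func:`adapt_delay` step is taken
    per firing.  With ``updates='cyclic'`` (the default) the time-multiplexed
    adaptor keeps re-applying its correction on every update cycle while the
    measurement holds, i.e. until the ramp saturates ``dmax - target`` cycles
    after the firing — which lets the proportional and one-step strategies
    converge to the measured value within a single presentation, and the
    single-count strategy crawl at one tick per cycle.
    """
    if config.updates == "single":
        return adapt_delay(config.strategy, delay, target, config.coefficient, dmax)
    budget = max(1, dmax - target)
    for _ in range(budget):
        new = adapt_delay(config.strategy, delay, target, config.coefficient, dmax)
        if new == delay:
            break
        delay = new
        if delay == target:
            break
    return delay


def _present_for_adaptation(
    net: Network,
    pattern: Pattern,
    addr_map: dict[int, list[int]],
    config: AdaptationConfig,
) -> None:
    """One teacher-forced presentation with the always-on delay adaptor.

    Every spike of the pattern restarts the ramp of *every* configured module
    whose input address matches — including modules storing other patterns —
    and each delay path whose output address fires later in the presentation
    (within the ramp range) is adapted toward that measured span.  This
    cross-pattern re-adaptation is what makes stored patterns interfere with
    each other in adaptation mode when address windows overlap.
    """
    from bisect import bisect_right

    dmax = net.params.delay_max_ticks
    times_by_addr: dict[int, list[int]] = {}
    for e in pattern.events:
        times_by_addr.setdefault(e.address, []).append(e.tick)
    for e in pattern.events:
        mods = addr_map.get(e.address)
        if not mods:
            continue
        t0 = e.tick
        for m in mods:
            outs = net.out_addrs[m]
            ds = net.delays[m]
            for j in range(4):
                b = outs[j]
                if b == UNSET:
                    continue
                ts = times_by_addr.get(b)
                if not ts:
                    continue
                i = bisect_right(ts, t0)
                if i == len(ts):
                    continue
                span = ts[i] - t0
                if span > dmax:
                    # the 9-bit ramp saturates before the firing: the adaptor
                    # sees the ceiling as its measurement
                    span = dmax
                ds[j] = _converged_update(config, ds[j], span, dmax)


def train_adaptation(
    net: Network,
    patterns: list[Pattern],
    config: AdaptationConfig,
) -> TrainingReport:
    """Train a pattern set by spike-timing-dependent delay adaptation.

    The first presentation of each pattern allocates module addresses exactly
    as programming does but draws the delays from ``init_delay_range`` (the
    latch is being written during that pass, so no adaptation happens yet).
    Every later presentation is teacher-forced — the full pattern is injected
    externally, so output firing times are the trained spike times — and
    drives the always-on delay adaptor of every matching configured module,
    including modules that store other patterns.  Addresses are written once
    and never touched again.
    """
    rng = np.random.default_rng(config.rng_seed)
    dmax = net.params.delay_max_ticks
    lo, hi = config.init_delay_range
    if hi > dmax:
        raise ParameterError("init_delay_range exceeds delay_max_ticks")
    total = TrainingReport()
    alloc: list[tuple[int, Pattern, int]] = []  # (module, pattern, spike index)
    addr_map: dict[int, list[int]] = {}
    for epoch in range(config.epochs):
        for p in patterns:
            if len(p) == 0:
                continue
            if epoch == 0:
                consumed, r = _allocate(net, p)
                total.modules_consumed += r.modules_consumed
                total.patterns_fully_stored += r.patterns_fully_stored
                total.patterns_partially_stored += r.patterns_partially_stored
                for idx, m in enumerate(consumed):
                    alloc.append((m, p, idx))
                    addr_map.setdefault(net.input_addrs[m], []).append(m)
                    for j in range(4):
                        if net.out_addrs[m][j] != UNSET:
                            net.delays[m][j] = int(rng.integers(lo, hi + 1))
                continue  # the configuring presentation only initializes
            _present_for_adaptation(net, p, addr_map, config)
        total.epoch_mean_abs_error.append(_mean_abs_error(net, alloc, dmax))
    net.invalidate_routing()
    return total


def _mean_abs_error(
    net: Network, alloc: list[tuple[int, Pattern, int]], dmax: int
) -> float:
    errs = []
    for m, p, k in alloc:
        for j in range(4):
            s = _span(p, k, j)
            if s is None:
                continue
            errs.append(abs(net.delays[m][j] - min(s, dmax)))
    return float(np.mean(errs)) if errs else 0.0


def enable_recall_adaptation(net: Network, config: AdaptationConfig) -> None:
    """Keep adapting delays while patterns are recalled (off by default).

    Every network-generated post-synaptic spike nudges the delays of all
    paths targeting that neuron whose module ramp is running and still below
    the ceiling — the hardware's always-on delay adaptor.
    """
    dmax = net.params.delay_max_ticks
    strategy, coef = config.strategy, config.coefficient

    def hook(network: Network, address: int, tick: int) -> None:
        if network._rev_map is None:
            network._build_rev_map()
        for m, j in network._rev_map.get(address, ()):
            start = network._ramp_start[m]
            if start == UNSET or tick < start:
                continue
            ramp = tick - start
            if ramp > dmax:
                continue
            network.delays[m][j] = adapt_delay(
                strategy, network.delays[m][j], ramp, coef, dmax
            )
            if network._sched is not None:
                network._sched[m] = [
                    (network.delays[m][jj], network.out_addrs[m][jj], jj)
                    for jj in range(4)
                    if network.out_addrs[m][jj] != UNSET
                    and 0 <= network.delays[m][jj] < dmax
                ]

    net._recall_adapt = hook


def disable_recall_adaptation(net: Network) -> None:
    net._recall_adapt = None
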