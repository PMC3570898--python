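"""Pattern generation and recall checking.

Spatio-temporal patterns are pseudo-random spike sequences produced by a pair
of maximal-length linear feedback shift registers: one LFSR (width matched to
the address bus, e.g. 7 bits for a 128-neuron array) picks the next neuron in
the sequence, a second fixed-width LFSR picks the inter-spike interval.  The
same seed pair regenerates the identical pattern for training and recall.

The recall checker mirrors the hardware pattern checker: for every reference
spike after the cue it opens a 4 ms acceptance pulse starting a random
0.5–1 ms before the reference time, and counts at most one address-matched
network spike per pulse.  A pattern is recalled successfully when the
coincident count is strictly greater than ``threshold`` times the number of
checked spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError, SpikeEvent, _is_pow2

__all__ = [
    "MAXIMAL_TAPS",
    "Lfsr",
    "Pattern",
    "RecallReport",
    "generate_pattern",
    "generate_pattern_sequence",
    "generate_noise",
    "check_recall",
    "INTERVAL_RANGE_DEFAULT",
    "CHECK_PULSE_TICKS",
    "CHECK_OFFSET_RANGE",
]

# Feedback tap positions (1-based bit indices) of one primitive polynomial per
# register width; any maximal-length choice reproduces the pattern statistics.
MAXIMAL_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
    8: (8, 7, 6, 1),
    9: (9, 5),
    10: (10, 7),
    11: (11, 9),
    12: (12, 11, 10, 4),
    13: (13, 12, 11, 8),
    14: (14, 13, 12, 2),
    15: (15, 14),
    16: (16, 15, 13, 4),
}

#: inter-spike interval bounds in ticks (~1-10 ms at the 62 us tick).  The
#: upper bound keeps every 3-interval span below the 511-tick delay ceiling so
#: each spike's three nearest delay paths are always representable.
INTERVAL_RANGE_DEFAULT: tuple[int, int] = (16, 160)

#: acceptance pulse length: 4 ms = 64 ticks
CHECK_PULSE_TICKS = 64
#: pulse early-offset bounds: 0.5-1 ms = 8-16 ticks (inclusive)
CHECK_OFFSET_RANGE: tuple[int, int] = (8, 16)

#: fixed width of the inter-spike-interval LFSR, shared by all network sizes
INTERVAL_LFSR_WIDTH = 12


class Lfsr:
    """Fibonacci linear feedback shift register with maximal-length taps."""

    def __init__(self, width: int, seed: int, taps: tuple[int, ...] | None = None):
        if width not in MAXIMAL_TAPS and taps is None:
            raise ParameterError(f"no tap table entry for width {width}")
        self.width = width
        self.taps = taps if taps is not None else MAXIMAL_TAPS[width]
        self.mask = (1 << width) - 1
        state = seed & self.mask
        if state == 0:
            raise ParameterError("LFSR state must be nonzero")
        self.state = state

    def next(self) -> int:
        """Advance one step and return the new register value (never 0)."""
        s = self.state
        bit = 0
        for t in self.taps:
            bit ^= (s >> (t - 1)) & 1
        s = ((s << 1) | bit) & self.mask
        self.state = s
        return s

    _jump_cache: dict[tuple[int, tuple[int, ...]], list[list[int]]] = {}

    def _jump_tables(self) -> list[list[int]]:
        """Successor tables for 2**i steps, built once per (width, taps)."""
        key = (self.width, self.taps)
        tables = Lfsr._jump_cache.get(key)
        if tables is None:
            n = self.mask + 1
            succ = [0] * n
            for s in range(1, n):
                bit = 0
                for t in self.taps:
                    bit ^= (s >> (t - 1)) & 1
                succ[s] = ((s << 1) | bit) & self.mask
            tables = [succ]
            bits = self.mask.bit_length()
            for _ in range(bits - 1):
                prev = tables[-1]
                tables.append([prev[prev[s]] for s in range(n)])
            Lfsr._jump_cache[key] = tables
        return tables

    def advance(self, steps: int) -> int:
        """Advance ``steps`` register steps (modulo the period); return state."""
        period = self.mask  # 2**width - 1 for a maximal-length register
        k = steps % period
        tables = self._jump_tables()
        s = self.state
        i = 0
        while k:
            if k & 1:
                s = tables[i][s]
            k >>= 1
            i += 1
        self.state = s
        return s

    def __iter__(self):
        return self

    __next__ = next


@dataclass(frozen=True)
class Pattern:
    """An ordered spatio-temporal spike sequence with strictly increasing ticks."""

    events: tuple[SpikeEvent, ...]
    pattern_id: int = 0
    seed_neuron: int = 0
    seed_interval: int = 0

    def __post_init__(self) -> None:
        ticks = [e.tick for e in self.events]
        if any(b <= a for a, b in zip(ticks, ticks[1:])):
            raise ParameterError("pattern ticks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> int:
        return self.events[-1].tick if self.events else 0


@dataclass(frozen=True)
class RecallReport:
    """Outcome of checking one recall trial against its reference pattern."""

    pattern_id: int
    n_reference_spikes: int
    n_checked: int
    n_coincident: int
    success: bool
    runaway: bool = False

    @property
    def spike_fraction(self) -> float:
        return self.n_coincident / self.n_checked if self.n_checked else 0.0


def _reduce_seed(seed: int, width: int) -> int:
    """Map an arbitrary integer seed to a valid nonzero register value."""
    return (seed % ((1 << width) - 1)) + 1


def generate_pattern(
    seed_neuron: int,
    seed_interval: int,
    n_neurons: int,
    n_intervals: int,
    interval_range: tuple[int, int] = INTERVAL_RANGE_DEFAULT,
    pattern_id: int = 0,
) -> Pattern:
    """Generate a pseudo-random pattern of ``n_intervals + 1`` spikes.

    Neuron indices come from an address-width LFSR, inter-spike intervals from
    a fixed-width LFSR mapped uniformly into ``interval_range`` (inclusive).
    The first spike is at tick 0.  Identical seeds give identical patterns;
    because the interval LFSR width is size-independent, the same seed pair
    yields the same interval sequence for every network size.
    """
    if n_intervals < 1:
        raise ParameterError("n_intervals must be >= 1")
    if not _is_pow2(n_neurons):
        raise ParameterError(
            f"n_neurons must be a power of two, got {n_neurons}"
        )
    width = n_neurons.bit_length() - 1
    lo, hi = interval_range
    if not (1 <= lo <= hi):
        raise ParameterError("invalid interval range")
    lfsr_addr = Lfsr(width, _reduce_seed(seed_neuron, width))
    lfsr_ivl = Lfsr(INTERVAL_LFSR_WIDTH, _reduce_seed(seed_interval, INTERVAL_LFSR_WIDTH))
    return _next_pattern(
        lfsr_addr, lfsr_ivl, n_neurons, n_intervals, interval_range,
        pattern_id, seed_neuron, seed_interval,
    )


def _next_pattern(
    lfsr_addr: Lfsr,
    lfsr_ivl: Lfsr,
    n_neurons: int,
    n_intervals: int,
    interval_range: tuple[int, int],
    pattern_id: int,
    seed_neuron: int,
    seed_interval: int,
) -> Pattern:
    # each spike draws one value from the interval register; it sets the
    # inter-spike interval AND the number of steps the address register jumps
    # before being sampled.  Patterns sit at different interval-register
    # phases, so their address sequences share neither a fixed successor
    # structure nor a global address-versus-time trajectory: stored patterns
    # overlap only diffusely, like independent random sequences
    lo, hi = interval_range
    span = hi - lo + 1
    tick = 0
    events = [SpikeEvent(0, lfsr_addr.next() % n_neurons)]
    for _ in range(n_intervals):
        v = lfsr_ivl.next()
        tick += lo + (v % span)
        events.append(SpikeEvent(tick, lfsr_addr.advance(v) % n_neurons))
    return Pattern(
        events=tuple(events),
        pattern_id=pattern_id,
        seed_neuron=seed_neuron,
        seed_interval=seed_interval,
    )


def generate_pattern_sequence(
    seed_neuron: int,
    seed_interval: int,
    n_neurons: int,
    n_intervals: int,
    n_patterns: int,
    interval_range: tuple[int, int] = INTERVAL_RANGE_DEFAULT,
) -> list[Pattern]:
    """Generate a run's whole pattern set from one seed pair.

    The two LFSRs run freely across pattern boundaries, as in the hardware
    pattern generator: the patterns of a run are consecutive windows of one
    register orbit, so their neuron addresses tile the array evenly and
    distinct patterns share no address subsequence until the orbit wraps.
    """
    if n_patterns < 1:
        raise ParameterError("n_patterns must be >= 1")
    if not _is_pow2(n_neurons):
        raise ParameterError(f"n_neurons must be a power of two, got {n_neurons}")
    width = n_neurons.bit_length() - 1
    lfsr_addr = Lfsr(width, _reduce_seed(seed_neuron, width))
    lfsr_ivl = Lfsr(INTERVAL_LFSR_WIDTH, _reduce_seed(seed_interval, INTERVAL_LFSR_WIDTH))
    out = []
    for i in range(n_patterns):
        if i:
            # one draw elapses across the inter-pattern gap
            lfsr_addr.advance(lfsr_ivl.next())
        out.append(
            _next_pattern(
                lfsr_addr, lfsr_ivl, n_neurons, n_intervals, interval_range,
                i, seed_neuron, seed_interval,
            )
        )
    return out


def generate_noise(
    rate_hz: float,
    duration_ticks: int,
    n_neurons: int,
    seed: int,
    tick_us: int = 62,
) -> list[SpikeEvent]:
    """Network-wide Poisson noise spikes at ``rate_hz`` total (not per neuron).

    Exponential inter-arrival times are quantized to ticks; each spike targets
    a uniformly random neuron.  Deterministic for a fixed seed.
    """
    if rate_hz < 0:
        raise ParameterError("noise rate must be >= 0")
    if rate_hz == 0 or duration_ticks <= 0:
        return []
    rng = np.random.default_rng(seed)
    ticks_per_s = 1_000_000.0 / tick_us
    mean_gap = ticks_per_s / rate_hz
    # draw ~4 sigma beyond the expectation, then trim
    n_draw = max(16, int(duration_ticks / mean_gap + 4 * (duration_ticks / mean_gap) ** 0.5 + 8))
    arrivals = np.cumsum(rng.exponential(mean_gap, size=n_draw))
    while arrivals[-1] < duration_ticks:  # pragma: no cover - very unlikely
        extra = np.cumsum(rng.exponential(mean_gap, size=n_draw)) + arrivals[-1]
        arrivals = np.concatenate([arrivals, extra])
    arrivals = arrivals[arrivals < duration_ticks]
    addresses = rng.integers(0, n_neurons, size=len(arrivals))
    return [
        SpikeEvent(int(t), int(a)) for t, a in zip(np.floor(arrivals), addresses)
    ]


def check_recall(
    reference: Pattern,
    cue_len: int,
    recalled: list[SpikeEvent],
    threshold: float = 0.70,
    seed: int = 0,
) -> RecallReport:
    """Score a recall trial against its reference pattern.

    For each reference spike after the cue, a 64-tick (4 ms) acceptance pulse
    opens a random 8-16 ticks before the reference tick.  The earliest unused
    network spike with a matching address inside the pulse counts as one
    coincidence; a spike is never counted twice.  Success requires the
    coincident count to be *strictly* greater than ``threshold`` times the
    number of checked spikes.
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must be in (0, 1)")
    checked = reference.events[cue_len:]
    n_checked = len(checked)
    rng = np.random.default_rng(seed)
    offsets = rng.integers(
        CHECK_OFFSET_RANGE[0], CHECK_OFFSET_RANGE[1] + 1, size=n_checked
    )
    # per-address sorted arrival ticks with used flags
    by_addr: dict[int, list[int]] = {}
    for ev in sorted(recalled, key=lambda e: e.tick):
        by_addr.setdefault(ev.address, []).append(ev.tick)
    used: dict[int, list[bool]] = {a: [False] * len(v) for a, v in by_addr.items()}
    n_coincident = 0
    for ev, off in zip(checked, offsets):
        start = ev.tick - int(off)
        end = start + CHECK_PULSE_TICKS
        ticks = by_addr.get(ev.address)
        if not ticks:
            continue
        flags = used[ev.address]
        for i, t in enumerate(ticks):
            if t >= end:
                break
            if t >= start and not flags[i]:
                flags[i] = True
                n_coincident += 1
                break
    return RecallReport(
        pattern_id=reference.pattern_id,
        n_reference_spikes=len(reference),
        n_checked=n_checked,
        n_coincident=n_coincident,
        success=n_coincident > threshold * n_checked,
    )
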