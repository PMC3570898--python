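"""Discrete-time core of the polychronous network.

The network has two populations wired through address-event buses:

* an array of coincidence-detector *neurons* — a neuron fires a post-synaptic
  spike when at least ``coincidence_threshold`` of its four synapse lines
  receive pre-synaptic spikes within ``coincidence_window_ticks`` of each
  other, after which it is refractory for ``refractory_ticks``;
* an array of *axon modules* — each module latches one input neuron address,
  four output addresses and four programmable delays.  A post-synaptic spike
  whose address matches a module's input address restarts that module's ramp
  counter; each delay path emits exactly one pre-synaptic spike on the tick
  the ramp reaches its latched delay.

Time is quantized to ticks of ``tick_us`` microseconds (62 us by default, the
update period of one time-multiplexed virtual axon module).  The simulator is
event-driven internally: between spikes nothing observable changes, so state
is advanced lazily, but :meth:`Network.step` exposes the canonical one-tick
semantics and produces identical spike streams.

Within a tick, events are resolved in a fixed deterministic order: pre-synaptic
deliveries (ascending module index, then delay-path index), then neuron
firings, then externally injected post-synaptic spikes; firings and injections
are routed back through the axon array immediately.  The firing delay of a
neuron models integration time as the sum of the elapsed values of its active
synapse timers at the moment the threshold-th spike arrives — zero when all
arrivals are simultaneous, up to ``2 * coincidence_window_ticks`` for maximally
dispersed arrivals.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "ParameterError",
    "SimParams",
    "SpikeEvent",
    "Network",
    "create_network",
    "integration_delay",
    "UNSET",
]

#: sentinel for unset addresses / delays / timers
UNSET = -1

# event priorities inside one tick
_PRE = 0
_FIRE = 1
_INJECT = 2


class ParameterError(ValueError):
    """Invalid parameter combination for the network or an operation."""


class SpikeEvent(NamedTuple):
    """One spike on an address-event bus.

    ``line`` is the synapse line (0-3) for pre-synaptic spikes and ``None``
    for post-synaptic spikes, which carry only the source neuron address.
    """

    tick: int
    address: int
    line: int | None = None


def _is_pow2(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class SimParams:
    """Static parameters of a simulated network.

    Defaults reproduce the reference configuration: a 4096-neuron array with
    one 4096-module axon array, 62 us ticks, a 1 ms coincidence window and
    refractory period (16 ticks), and a 9-bit delay range (511 ticks, ~32 ms).
    """

    n_neurons: int = 4096
    n_axon_arrays: int = 1
    modules_per_array: int = 4096
    tick_us: int = 62
    fanout: int = 4
    coincidence_threshold: int = 3
    coincidence_window_ticks: int = 16
    refractory_ticks: int = 16
    delay_max_ticks: int = 511
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not _is_pow2(self.n_neurons):
            raise ParameterError(
                f"n_neurons must be a power of two (address-width semantics), "
                f"got {self.n_neurons}"
            )
        if self.n_neurons < 4:
            raise ParameterError("n_neurons must be at least 4")
        if self.n_axon_arrays < 1:
            raise ParameterError("n_axon_arrays must be >= 1")
        if self.modules_per_array < 1:
            raise ParameterError("modules_per_array must be >= 1")
        if self.fanout != 4:
            raise ParameterError("fanout is fixed at 4 delay paths per module")
        if not (1 <= self.coincidence_threshold <= self.fanout):
            raise ParameterError(
                f"coincidence_threshold must be in [1, {self.fanout}], "
                f"got {self.coincidence_threshold}"
            )
        if self.coincidence_window_ticks < 1:
            raise ParameterError("coincidence_window_ticks must be >= 1")
        if self.refractory_ticks < 0:
            raise ParameterError("refractory_ticks must be >= 0")
        if not _is_pow2(self.delay_max_ticks + 1):
            raise ParameterError(
                "delay_max_ticks must be 2**delay_bits - 1 (counter semantics)"
            )
        if self.tick_us <= 0:
            raise ParameterError("tick_us must be positive")

    @property
    def n_modules(self) -> int:
        return self.n_axon_arrays * self.modules_per_array

    @property
    def delay_bits(self) -> int:
        return (self.delay_max_ticks + 1).bit_length() - 1

    @property
    def ticks_per_second(self) -> float:
        return 1_000_000.0 / self.tick_us


def integration_delay(timer_elapsed_values: Iterable[int]) -> int:
    """Integration time of a coincidence detector: the sum of the elapsed
    values of the synapse timers active when the threshold-th pre-synaptic
    spike arrives.

    Dispersed arrivals integrate longer than simultaneous ones, emulating a
    biological coincidence detector.  The hardware realizes this sum at
    system-clock granularity, so on the 62 us tick grid the delay is sub-tick:
    the simulator emits the output spike on the threshold tick itself and this
    function serves as a diagnostic of arrival dispersion.
    """
    return sum(timer_elapsed_values)


class Network:
    """A polychronous network: axon-module table plus live neuron state.

    The learned structure lives entirely in the module table
    (``input_addrs``, ``out_addrs``, ``delays``); neuron state and the event
    queue are transient and reset by :meth:`reset_dynamics`.
    """

    def __init__(self, params: SimParams):
        self.params = params
        m = params.n_modules
        self.input_addrs: list[int] = [UNSET] * m
        # out_addrs[i][j] / delays[i][j]: path j of module i
        self.out_addrs: list[list[int]] = [[UNSET] * 4 for _ in range(m)]
        self.delays: list[list[int]] = [[UNSET] * 4 for _ in range(m)]
        self.programming_index = 0
        self.current_tick = 0
        # routing caches, rebuilt after any training
        self._addr_map: dict[int, list[int]] | None = None
        self._sched: list[list[tuple[int, int, int]]] | None = None
        # dynamic state
        self._heap: list[tuple[int, int, int, int, int, int]] = []
        self._gen = [0] * m
        self._ramp_start = [UNSET] * m
        self._timers = [[UNSET] * 4 for _ in range(params.n_neurons)]
        self._window_start = [UNSET] * params.n_neurons
        self._pending = [UNSET] * params.n_neurons
        self._refract_until = [0] * params.n_neurons
        self.emitted: list[SpikeEvent] = []
        self.runaway = False
        # optional on-recall plasticity hook, set by plasticity.enable_recall_adaptation
        self._recall_adapt = None
        self._rev_map: dict[int, list[tuple[int, int]]] | None = None

    # ------------------------------------------------------------------ setup

    @property
    def configured_count(self) -> int:
        return self.programming_index

    def invalidate_routing(self) -> None:
        """Drop routing caches after the module table changed."""
        self._addr_map = None
        self._sched = None
        self._rev_map = None

    def _build_routing(self) -> None:
        dmax = self.params.delay_max_ticks
        amap: dict[int, list[int]] = {}
        sched: list[list[tuple[int, int, int]]] = []
        for i in range(self.programming_index):
            a = self.input_addrs[i]
            if a != UNSET:
                amap.setdefault(a, []).append(i)
            entries = []
            outs = self.out_addrs[i]
            ds = self.delays[i]
            for j in range(4):
                d = ds[j]
                # a saturated delay (== delay_max) never emits: the 9-bit ramp
                # stops at its ceiling and the comparator cannot pass it
                if outs[j] != UNSET and 0 <= d < dmax:
                    entries.append((d, outs[j], j))
            sched.append(entries)
        sched.extend([] for _ in range(self.params.n_modules - len(sched)))
        self._addr_map = amap
        self._sched = sched

    def _build_rev_map(self) -> None:
        rev: dict[int, list[tuple[int, int]]] = {}
        for i in range(self.programming_index):
            for j in range(4):
                tgt = self.out_addrs[i][j]
                if tgt != UNSET:
                    rev.setdefault(tgt, []).append((i, j))
        self._rev_map = rev

    def reset_dynamics(self) -> None:
        """Clear all transient state; the trained structure is untouched."""
        self._heap.clear()
        n = self.params.n_neurons
        self._timers = [[UNSET] * 4 for _ in range(n)]
        self._window_start = [UNSET] * n
        self._pending = [UNSET] * n
        self._refract_until = [0] * n
        self._ramp_start = [UNSET] * self.params.n_modules
        self.emitted = []
        self.runaway = False
        self.current_tick = 0

    # ------------------------------------------------------------- primitives

    def axon_receive(self, address: int, tick: int | None = None) -> int:
        """Present a post-synaptic spike to the axon array.

        Every configured module whose input address matches restarts its ramp
        (cancelling any still-pending emissions of the previous activation)
        and schedules one pre-synaptic spike per configured, non-saturated
        delay path.  Returns the number of matching modules; multiple matches
        occur when an address appears in several stored patterns.
        """
        if not (0 <= address < self.params.n_neurons):
            raise ParameterError(f"address {address} out of range")
        if tick is None:
            tick = self.current_tick
        if self._addr_map is None:
            self._build_routing()
        matches = self._addr_map.get(address)
        if not matches:
            return 0
        heap = self._heap
        gen = self._gen
        sched = self._sched
        for m in matches:
            g = gen[m] + 1
            gen[m] = g
            self._ramp_start[m] = tick
            for d, out, j in sched[m]:
                heapq.heappush(heap, (tick + d, _PRE, m, j, g, out))
        return len(matches)

    def neuron_receive(self, address: int, line: int, tick: int) -> None:
        """Deliver a pre-synaptic spike to one synapse line of a neuron.

        The first spike arriving at an idle neuron opens a coincidence window
        of ``coincidence_window_ticks``; when the window expires without the
        threshold being met, all synapse timers clear together and the neuron
        returns to idle (the controller frees its physical neuron 1 ms after
        assignment).  Within a window, a spike on an already-active line is
        ignored.  Reaching the threshold schedules a post-synaptic spike after
        the integration delay and starts the refractory period.
        """
        if not (0 <= line < 4):
            raise ParameterError(f"synapse line {line} out of range")
        if not (0 <= address < self.params.n_neurons):
            raise ParameterError(f"address {address} out of range")
        if self._pending[address] != UNSET or tick < self._refract_until[address]:
            return
        w = self.params.coincidence_window_ticks
        ts = self._timers[address]
        ws = self._window_start[address]
        if ws == UNSET or tick - ws > w:
            # stale assignment: free the neuron and open a fresh window
            ts[0] = ts[1] = ts[2] = ts[3] = UNSET
            self._window_start[address] = tick
        if ts[line] != UNSET:
            return  # timer already active: spike is ignored
        ts[line] = tick
        count = 0
        for l in range(4):
            if ts[l] != UNSET:
                count += 1
        if count >= self.params.coincidence_threshold:
            # the integration delay (sum of timer values) is clock-cycle
            # scale in the hardware, i.e. microseconds: sub-tick here, so the
            # output spike lands on the same tick as the threshold-th input
            fire_tick = tick
            self._pending[address] = fire_tick
            self._refract_until[address] = fire_tick + self.params.refractory_ticks
            ts[0] = ts[1] = ts[2] = ts[3] = UNSET
            self._window_start[address] = UNSET
            heapq.heappush(self._heap, (fire_tick, _FIRE, address, 0, 0, 0))

    def inject(self, events: Iterable[SpikeEvent]) -> None:
        """Queue external post-synaptic spikes (cues, training input, noise)."""
        for ev in events:
            if not (0 <= ev.address < self.params.n_neurons):
                raise ParameterError(
                    f"injected address {ev.address} out of range for "
                    f"{self.params.n_neurons} neurons"
                )
            if ev.tick < self.current_tick:
                raise ParameterError("cannot inject events in the past")
            heapq.heappush(self._heap, (ev.tick, _INJECT, ev.address, 0, 0, 0))

    # ---------------------------------------------------------------- running

    def _dispatch(self, item: tuple[int, int, int, int, int, int]) -> None:
        tick, prio, a, b, c, d = item
        if prio == _PRE:
            # a=module, b=path, c=generation, d=target address
            if self._gen[a] == c:
                self.neuron_receive(d, b, tick)
        elif prio == _FIRE:
            self._pending[a] = UNSET
            self.emitted.append(SpikeEvent(tick, a))
            if self._recall_adapt is not None:
                self._recall_adapt(self, a, tick)
            self.axon_receive(a, tick)
        else:  # _INJECT
            self.axon_receive(a, tick)

    def step(self) -> list[SpikeEvent]:
        """Advance exactly one tick; return post-synaptic spikes emitted."""
        t = self.current_tick
        n_before = len(self.emitted)
        heap = self._heap
        while heap and heap[0][0] == t:
            self._dispatch(heapq.heappop(heap))
        self.current_tick = t + 1
        return self.emitted[n_before:]

    def run(self, until_tick: int, max_spikes: int | None = None) -> list[SpikeEvent]:
        """Run until the queue drains or ``until_tick`` is passed.

        Equivalent to calling :meth:`step` in a loop, but silent stretches are
        skipped.  If ``max_spikes`` is given and exceeded, the run aborts with
        ``self.runaway`` set — the guard against the all-neurons-fire
        cross-talk state of overloaded small networks.
        """
        heap = self._heap
        emitted = self.emitted
        while heap and heap[0][0] <= until_tick:
            if max_spikes is not None and len(emitted) > max_spikes:
                self.runaway = True
                break
            self._dispatch(heapq.heappop(heap))
        self.current_tick = max(self.current_tick, until_tick + 1)
        return emitted


def create_network(params: SimParams) -> Network:
    """Build an empty network: all modules unconfigured, all neurons idle."""
    return Network(params)
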