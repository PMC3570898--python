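# Model and methods

`polychron` simulates a polychronous spiking neural network: a content-
addressable memory for spatio-temporal spike patterns in which the learned
structure lives entirely in programmable axonal delays. This note describes
the model, the discretization choices, the training rules, the synthetic
pattern generator, and what the shipped experiments do and do not show.

## The network

Two populations communicate over address-event buses:

**Coincidence-detector neurons.** Each neuron has four synapse lines and no
membrane dynamics. The first pre-synaptic spike arriving at an idle neuron
opens a coincidence window of 1 ms (16 ticks); a spike on an already-active
line within the window is ignored; if three distinct lines receive spikes
inside the window, the neuron emits a post-synaptic spike and becomes
refractory for 1 ms; if the window expires first, all four synapse timers
clear together and the neuron returns to idle. The all-clear-at-expiry
(anchored window) semantics mirrors the way a time-multiplexed controller
assigns a physical detector to an address for exactly one window; it is
deliberately stricter than per-line sliding timers, which would let long
staggered chains of unrelated arrivals accumulate to threshold.

**Axon modules.** A module is the unit of storage: one write-once input
address, four write-once output addresses, and four delay registers of 9 bits
(0–511 ticks, ≈32 ms at the 62 µs tick). A post-synaptic spike whose address
matches a module's input restarts that module's ramp counter (cancelling any
still-pending emissions of the previous activation — at most one spike per
path per activation). A delay path emits its pre-synaptic spike on the tick
the ramp *reaches* its latched delay; a path whose latched delay equals the
ramp ceiling never emits, because the saturating counter stops there. This
is how spans too long for 9 bits are stored: clamped to the ceiling and
silent, rather than mis-timed.

**Time.** One tick is 62 µs, the update period of a time-multiplexed virtual
axon module (4096 modules at 66 MHz). All delays, windows and refractory
periods are integers in this unit. The simulator is event-driven internally
(a heap of pre-synaptic, post-synaptic and injected events with a fixed
deterministic within-tick order: deliveries by ascending module and path
index, then firings, then injections), which is exactly equivalent to the
tick-stepped semantics exposed by `Network.step()` — the test suite checks
this equivalence against a brute-force tick-scan simulator on small random
instances.

**Integration delay.** A biological coincidence detector fires later when
its inputs are dispersed. The hardware analogue sums the synapse-timer
values when the third spike arrives — but at system-clock granularity
(15 ns), i.e. microseconds: far below one tick. The simulator therefore
fires the neuron on the tick the threshold is reached, and exposes
`integration_delay()` (the timer sum) as a dispersion diagnostic only.
This choice matters: if the timer sum were applied as a delay in ticks, the
firing time would amplify arrival dispersion threefold per hop
(fire = 3·a₍₃₎ − a₍₁₎ − a₍₂₎), and any chain with even ±1-tick delay errors
— every delay-adaptation run — would drift out of its checker window within
a few spikes. With sub-tick integration, a perfectly programmed pattern is
recalled *exactly* time-locked to its trained ticks.

## Training

**Delay programming.** Each spike of a training pattern consumes the next
unconfigured module (the programming index advances once per spike and never
decreases): the module latches the spike's address as input, the next four
pattern spikes as outputs, and the corresponding tick spans as delays. A
pattern of L spikes consumes L modules, so the capacity of M modules is
⌊M/L⌋ patterns, and one pass stores a pattern exactly; spans beyond 511
ticks are clamped (silent paths) and counted in the training report.

**Delay adaptation.** The first presentation allocates addresses exactly as
programming does but initializes the delays uniformly at random in
[1, 511]. Every later presentation is teacher-forced — the whole pattern is
driven externally, so firing times equal trained times — and the delay
adaptor compares each running ramp with the firing of its path's output
neuron. Three step-size strategies set the correction per measurement:
`one_step` (jump to the measured value; equivalent to programming),
`single_count` (±1 tick), and `proportional` (a fraction `coefficient`,
default 0.5, of the remaining difference, rounded half-away-from-zero so a
nonzero error always moves). Because the time-multiplexed adaptor is
updated serially and cyclically, the default `updates="cyclic"` mode
re-applies the correction once per update cycle while the measurement holds
(until the ramp saturates), so the proportional rule converges to the
measured span within one presentation; `updates="single"` applies exactly
one correction per firing, which makes the per-epoch error decay
geometrically as (1−c)^(k−1) — the regime the property tests pin down.

Two consequences of the adaptor being *always on* shape the results. First,
while pattern B is being trained, any module of a previously stored pattern
A whose input address happens to occur in B also measures and adapts — its
delays are corrupted toward B's timing wherever B contains its output
addresses within the ramp range. This cross-pattern corruption grows with
the address-collision rate, i.e. with (patterns × length)/n_neurons, and is
why adaptation mode needs roughly an order of magnitude fewer connections
per neuron than programming mode for the same recall quality. Second, the
same mechanism can optionally run during recall
(`enable_recall_adaptation`), letting stored delays track slowly drifting
patterns; it is off by default in all experiments.

## Pattern generation and checking

Patterns are produced by two maximal-length Fibonacci LFSRs with verified
tap sets (widths 2–16; the address register width equals log₂ n_neurons, so
7 bits for 128 neurons up to 12 bits for 4096; the interval register is
fixed at 12 bits for all sizes, so a seed reproduces the same interval
sequence at every size). One seed pair generates a whole run's pattern set:
the registers free-run across pattern boundaries. Each spike draws one
value v from the interval register; the inter-spike interval is
16 + (v mod 145) ticks — uniform on ≈1–10 ms — and the address register
jumps v steps before being sampled for the spike's neuron index.

Both halves of that construction are load-bearing:

* The interval upper bound (160 ticks) keeps every 3-interval span ≤ 480 <
  511 ticks, so each spike's three nearest delay paths are always
  representable in 9 bits; the 4-interval path saturates ≈3% of the time,
  benignly silent. A wider interval range (e.g. ≈1–19 ms) would silence the
  third-nearest path almost half the time and starve the threshold-3 chain.
* Driving the address jump from the raw interval draw decorrelates patterns
  from each other in both structure and time. If the address register
  instead stepped once per spike, all patterns would be windows of a single
  orbit and recall would be hijacked by coherent "ghost" chains; if it
  advanced by the interval *in ticks*, the address would become a global
  function of elapsed time and all cross-talk would land time-locked on one
  trajectory, detonating the all-fire state even in mid-sized arrays. With
  interval-driven jumps, stored patterns overlap diffusely, like
  independent random sequences, and interference is governed by the mean
  number of connections per neuron — small relative to n/4 in the regimes
  where recall succeeds, which is the sparsity rule the experiments verify.

Noise is a network-wide Poisson process (total rate in Hz, not per neuron):
exponential inter-arrivals quantized to ticks, uniform random addresses,
drawn from a seeded PCG64 generator. The contract is statistics-level
reproduction, not register-level identity with any particular hardware
noise source.

**Recall checking.** A trial injects the first four spikes of a stored
pattern at their trained relative ticks (plus noise, if any) and lets the
network run for the trained duration plus ten delay ceilings, enough for
residual activity to die out. For every reference spike after the cue the
checker opens a 64-tick (4 ms) acceptance pulse starting a seeded-uniform
8–16 ticks (0.5–1 ms) before the reference tick; the earliest unused
network spike with a matching address inside the pulse counts once. A
pattern is successfully recalled when the coincident count strictly exceeds
70% of the checked spikes. A trial aborts and scores as failure (fraction
0) if the network emits more than 50 spikes per pattern spike — the guard
that detects the all-fire cross-talk state of overloaded small arrays
without hanging the run.

## Experiments and their scales

All sweeps share one protocol: per configuration and per seeded run,
generate the pattern set from one LFSR seed pair, train a fresh network,
recall every pattern once, and score at the strict 70% threshold. A master
seed expands into the 10 per-run seeds through numpy's `SeedSequence`;
every random choice (LFSR seeds, adaptation initialization, noise, checker
offsets) descends from the run seed, so identical seed lists reproduce
results byte-for-byte. Reported standard deviations are across runs, never
across patterns.

* **Size sweep** — 82 patterns × 50 intervals on one 4096-module axon
  array, neuron arrays 128–4096. 82 patterns slightly exceed the floor
  capacity of 80, so the two trailing patterns are partially stored or
  unstored and bound success near 80/82 ≈ 97.6% even in the cleanest runs.
* **Noise sweep** — the 4096-neuron configuration, rates 2–128 Hz, noise
  present only during recall (training is noiseless). Under the ideal
  lossless bus assumed throughout (no address collisions, no serialization
  losses), the surviving noise mechanisms — ramp restarts of in-use modules
  and diffuse spurious arrivals — degrade recall only weakly even at
  128 Hz; hardware with a shared arbiter-less bus degrades faster. The
  shipped check is therefore directional: monotone non-increasing success,
  near-noiseless below 32 Hz (programming) and 16 Hz (adaptation).
* **Full-capacity test** — pattern counts equal to ⌊M/L⌋ for L ∈ {21, 51}
  spikes in both training modes. The default desk scale shrinks the 70
  axon arrays to 7 (28 672 modules, 562 or 1365 patterns) while keeping the
  4096-neuron array, per-run cost ≈25 s; connections per neuron are then 28
  rather than the full-scale 280, so the desk-scale run probes
  proportionally less cross-talk than a full-scale run — its success rates
  should be read as the method's behavior at one tenth of maximum load,
  compared against the published full-load figures at scaled-down
  tolerance. `--scale 1` reproduces the full configuration when hours of
  runtime are acceptable.

## What the synthetic patterns do not capture

LFSR patterns are temporally uniform and address-uniform: no bursting, no
refractory structure in the input, no rate modulation, no correlation
between patterns beyond chance. Recall statistics on such patterns measure
the storage substrate — delay precision, coincidence robustness,
cross-talk — not performance on naturalistic spike trains, whose
correlations would increase connection sharing and cross-talk beyond the
diffuse-overlap regime studied here.

## Numerical and degenerate-input policy

Ticks, addresses and delays are exact integers; there is no floating-point
state in the dynamics. Ties inside a tick are broken by fixed priority
(deliveries, then firings, then injections) and ascending module/path or
neuron index; all results are bit-reproducible for a fixed seed. Empty
patterns are no-ops; a pattern presented after module exhaustion configures
nothing and is reported unstored; delays edited beyond the 9-bit range are
rejected at snapshot load; the all-zero LFSR state is rejected at
construction (address 0 consequently never occurs in generated patterns —
one of 4096 addresses idle, invisible at the statistics level).

## Known limitations

* The bus is ideal: no AER collisions, no one-spike-per-update-cycle
  serialization, no cap on simultaneously active modules or physical
  neurons. This widens the gap between simulated and hardware noise
  robustness (see above) and removes the hardware's throughput ceiling.
* Delay adaptation's cyclic convergence abstracts the adaptor's per-cycle
  arithmetic; hardware convergence within one presentation is exact only
  when the ramp has enough cycles left after the output fires, which the
  simulator honors by budgeting updates until ramp saturation.
* The desk-scale capacity test preserves module count per pattern but not
  connections per neuron (see above).
* Patterns with more than ~60 intervals were not characterized; longer
  patterns accumulate more opportunities for chain breaks and recall
  success declines gradually with length.
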