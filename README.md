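# polychron

A discrete-event simulator of a **polychronous spiking neural network**: a
short-term memory for spatio-temporal spike patterns in which information is
stored not in synaptic weights but in **programmable axonal delays**.

Polychronization is the phenomenon in which source neurons fire
*asynchronously*, yet their spikes — each travelling down an axon with its
own conduction delay — arrive at a shared target neuron *simultaneously* and
make it fire. A network built on this principle can store a spike pattern by
setting delays so that every spike in the pattern is regenerated, at the
right time, by the coincidence of its predecessors. Presenting only the
first few spikes of a stored pattern (the cue) then replays the rest,
time-locked to the trained schedule. The package is aimed at computational
and neuromorphic-engineering researchers who want to study the capacity,
cross-talk and noise behavior of delay-based pattern memories without
hardware in the loop.

## Model

* **Neurons** are pure coincidence detectors with four synapse lines: a
  neuron fires iff spikes arrive on ≥ 3 distinct lines within a 1 ms window
  (16 ticks of 62 µs), then stays refractory for 1 ms. There is no membrane
  potential.
* **Axon modules** are the storage units. Module *i* holds one input
  address, four output addresses and four 9-bit delays d₀…d₃ ∈ [0, 511]
  ticks (≤ ≈32 ms). A post-synaptic spike matching the input address
  restarts the module's ramp counter; delay path *j* emits one pre-synaptic
  spike to output *j* (synapse line *j*) when the ramp reaches dⱼ.
* **Delay programming** stores a pattern in one pass: the module consumed by
  spike *k* latches dⱼ = t(k+1+j) − t(k), the inter-spike spans to the next
  four spikes. A pattern of L spikes consumes L modules, so M modules store
  ⌊M/L⌋ patterns.
* **Delay adaptation** (spike-timing-dependent delay plasticity) starts from
  random delays and corrects each one toward the measured timing difference
  between a module's ramp start and its output neuron's firing:
  d ← d + round(c · (ramp_at_fire − d)) with coefficient c = 0.5 by default;
  one-step and single-count variants are included.
* **Patterns** come from two maximal-length LFSRs (the hardware's pattern
  generator): one register, as wide as the address bus, picks neuron
  indices; a fixed 12-bit register draws inter-spike intervals uniform on
  ≈1–10 ms. A recall trial injects the first four spikes and scores the
  replay with 4 ms acceptance pulses; success requires > 70% of the
  remaining spikes to be regenerated on time.

See `docs/methods.md` for the discretization choices (62 µs tick, anchored
coincidence windows, sub-tick integration delay), the always-on adaptor and
its cross-pattern interference, and what the LFSR patterns do and do not
represent.

## Worked example

```python
from polychron import (SimParams, create_network, generate_pattern,
                       program_pattern, run_recall_trial)

params = SimParams(n_neurons=4096)          # one 4096-module axon array
net = create_network(params)
pattern = generate_pattern(seed_neuron=2024, seed_interval=716,
                           n_neurons=4096, n_intervals=50)
report = program_pattern(net, pattern)
print(f"stored {len(pattern)} spikes in {report.modules_consumed} modules "
      f"({report.spans_clamped} spans clamped at the 32 ms ceiling)")

recall = run_recall_trial(net, pattern, noise_rate_hz=32.0, seed=7)
print(f"recalled {recall.n_coincident}/{recall.n_checked} spikes "
      f"(fraction {recall.spike_fraction:.2f}) -> success={recall.success}")
```

prints

```
stored 51 spikes in 51 modules (1 spans clamped at the 32 ms ceiling)
recalled 47/47 spikes (fraction 1.00) -> success=True
```

The 51-spike pattern consumed 51 modules; one of the 200 delay paths spanned
more than 32 ms and was stored saturated (permanently silent — the safe
representation of an unprogrammable span). Cued with its first four spikes
and perturbed by 32 Hz Poisson noise, the network regenerated all 47
remaining spikes inside their 4 ms checker pulses, so the pattern counts as
successfully recalled at the strict 70% threshold.

## Command line

The same experiments are available as subcommands, each writing tidy CSVs
plus a JSON manifest with every seed used:

```sh
polychron generate-patterns --n 82 --intervals 50 --neurons 4096 --seed 42 --out pats/
polychron train --patterns-dir pats/ --mode programming --neurons 4096 --out net.snap
polychron recall --snapshot net.snap --patterns-dir pats/ --out recall.csv
polychron sweep-size  --runs 10 --seed 42 --out results/size/
polychron sweep-noise --runs 10 --seed 42 --out results/noise/
polychron capacity-test --scale 0.1 --runs 10 --seed 42 --out results/capacity/
```

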