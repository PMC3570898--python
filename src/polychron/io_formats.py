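"""Plain-text readers and writers: spike events, snapshots, configs, manifests.

Everything is diff-able text.  Spike-event files are delimited text with a
header (``tick,address[,line]``); network snapshots are structured key/value
plus one record per configured module, sufficient to round-trip a trained
network exactly; experiment configs are YAML; run manifests are JSON with
output checksums so a run can be re-executed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable

import yaml

from .core import UNSET, Network, SimParams, SpikeEvent, create_network

__all__ = [
    "FormatError",
    "read_events",
    "write_events",
    "save_snapshot",
    "load_snapshot",
    "write_manifest",
    "read_manifest",
    "load_config",
    "save_config",
]

SNAPSHOT_VERSION = 1
EVENTS_HEADER = "tick,address,line"


class FormatError(ValueError):
    """Malformed or inconsistent file content."""


# ------------------------------------------------------------------- events


def write_events(path: str | Path, events: Iterable[SpikeEvent]) -> None:
    """Write a tick-sorted spike-event stream as delimited text."""
    lines = [EVENTS_HEADER]
    prev = None
    for ev in events:
        if prev is not None and ev.tick < prev:
            raise FormatError("events must be tick-sorted")
        prev = ev.tick
        line = "" if ev.line is None else str(ev.line)
        lines.append(f"{ev.tick},{ev.address},{line}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: str | Path, n_neurons: int | None = None) -> list[SpikeEvent]:
    """Read a spike-event file; validates sorting and (optionally) addresses."""
    text = Path(path).read_text()
    raw = text.splitlines()
    if not raw or raw[0].strip() != EVENTS_HEADER:
        raise FormatError(f"{path}: missing header line {EVENTS_HEADER!r}")
    events: list[SpikeEvent] = []
    prev = None
    for lineno, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 fields")
        try:
            tick = int(parts[0])
            address = int(parts[1])
            syn = None
            if len(parts) == 3 and parts[2].strip() != "":
                syn = int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if tick < 0:
            raise FormatError(f"{path}:{lineno}: negative tick")
        if prev is not None and tick < prev:
            raise FormatError(f"{path}:{lineno}: events not tick-sorted")
        if syn is not None and not (0 <= syn < 4):
            raise FormatError(f"{path}:{lineno}: synapse line out of range")
        if n_neurons is not None and not (0 <= address < n_neurons):
            raise FormatError(
                f"{path}:{lineno}: address {address} out of range for "
                f"{n_neurons} neurons"
            )
        prev = tick
        events.append(SpikeEvent(tick, address, syn))
    return events


# ----------------------------------------------------------------- snapshot


def save_snapshot(path: str | Path, net: Network) -> None:
    """Serialize the trained structure (params + configured modules)."""
    lines = [f"# polychron network snapshot v{SNAPSHOT_VERSION}"]
    lines.append(f"format_version={SNAPSHOT_VERSION}")
    for f in dataclasses.fields(SimParams):
        lines.append(f"{f.name}={getattr(net.params, f.name)}")
    lines.append(f"programming_index={net.programming_index}")
    for m in range(net.programming_index):
        outs = " ".join(str(a) for a in net.out_addrs[m])
        ds = " ".join(str(d) for d in net.delays[m])
        lines.append(f"module {m} {net.input_addrs[m]} {outs} {ds}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_snapshot(path: str | Path) -> Network:
    """Rebuild a network from a snapshot, enforcing all invariants."""
    raw = Path(path).read_text().splitlines()
    kv: dict[str, str] = {}
    modules: list[tuple[int, list[int]]] = []
    for lineno, line in enumerate(raw, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("module "):
            parts = line.split()
            if len(parts) != 11:
                raise FormatError(f"{path}:{lineno}: malformed module record")
            try:
                values = [int(x) for x in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            modules.append((lineno, values))
        elif "=" in line:
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        else:
            raise FormatError(f"{path}:{lineno}: unrecognized line")
    if kv.get("format_version") != str(SNAPSHOT_VERSION):
        raise FormatError(
            f"{path}: unsupported snapshot version {kv.get('format_version')!r}"
        )
    try:
        params = SimParams(
            **{
                f.name: type(getattr(SimParams(), f.name))(kv[f.name])
                for f in dataclasses.fields(SimParams)
            }
        )
        programming_index = int(kv["programming_index"])
    except KeyError as exc:
        raise FormatError(f"{path}: truncated snapshot, missing {exc}") from exc
    net = create_network(params)
    if not (0 <= programming_index <= params.n_modules):
        raise FormatError(f"{path}: programming_index out of range")
    if len(modules) != programming_index:
        raise FormatError(
            f"{path}: expected {programming_index} module records, "
            f"found {len(modules)}"
        )
    for lineno, vals in modules:
        idx, inp, o0, o1, o2, o3, d0, d1, d2, d3 = vals
        if not (0 <= idx < params.n_modules):
            raise FormatError(f"{path}:{lineno}: module index out of range")
        for a in (inp, o0, o1, o2, o3):
            if a != UNSET and not (0 <= a < params.n_neurons):
                raise FormatError(f"{path}:{lineno}: address out of range")
        for d in (d0, d1, d2, d3):
            if d != UNSET and not (0 <= d <= params.delay_max_ticks):
                raise FormatError(
                    f"{path}:{lineno}: delay {d} exceeds delay_max_ticks"
                )
        net.input_addrs[idx] = inp
        net.out_addrs[idx] = [o0, o1, o2, o3]
        net.delays[idx] = [d0, d1, d2, d3]
    net.programming_index = programming_index
    net.invalidate_routing()
    return net


# ----------------------------------------------------------------- manifest


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seeds: list[int],
    output_files: Iterable[str | Path] = (),
) -> None:
    """Record everything needed to re-execute a run bit-identically."""
    manifest = {
        "artifact": "polychron",
        "version": "0.1.0",
        "config": config,
        "seeds": list(seeds),
        "checksums": {str(p): _sha256(p) for p in output_files},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------------- config


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment config as a plain dict."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


def save_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
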