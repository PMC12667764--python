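"""Labeled 4-D simulation output (time x state x region x mode) and its I/O.

Region-based simulations always have a single mode; the fourth axis is kept
so that downstream observation graphs operate on one fixed rank.  Export is
offered both as delimited text (one column per state/region pair) and as a
self-describing binary container (NumPy ``.npz`` with label arrays); both
round-trip through the corresponding reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


def expand_to_4d(data: np.ndarray) -> np.ndarray:
    """Expand an array to four axes (time x state x region x mode).

    Missing trailing axes are appended with length 1; this shape-safety
    step avoids broadcasting ambiguity in observation graphs.
    """
    data = np.asarray(data)
    if data.ndim > 4:
        raise ValueError(f"rank {data.ndim} > 4")
    while data.ndim < 4:
        data = data[..., np.newaxis]
    return data


@dataclass
class TimeSeries4D:
    data: np.ndarray
    time: np.ndarray
    state_labels: list
    region_labels: list
    sample_period: float
    transient: float = 0.0
    mode_labels: list = field(default_factory=lambda: ["mode_0"])

    def __post_init__(self):
        self.data = expand_to_4d(self.data)
        self.time = np.asarray(self.time, dtype=float)
        nt, ns, nr, nm = self.data.shape
        if len(self.time) != nt:
            raise ValueError(f"{len(self.time)} time points for {nt} samples")
        if len(self.state_labels) != ns:
            raise ValueError(f"{len(self.state_labels)} state labels for {ns} states")
        if len(self.region_labels) != nr:
            raise ValueError(f"{len(self.region_labels)} region labels for {nr} regions")
        if len(self.mode_labels) != nm:
            self.mode_labels = [f"mode_{i}" for i in range(nm)]

    @property
    def n_times(self):
        return self.data.shape[0]

    def state_index(self, name: str) -> int:
        return self.state_labels.index(name)

    def select_states(self, names: Sequence[str]) -> "TimeSeries4D":
        idx = [self.state_index(n) for n in names]
        return TimeSeries4D(
            data=self.data[:, idx],
            time=self.time,
            state_labels=[self.state_labels[i] for i in idx],
            region_labels=self.region_labels,
            sample_period=self.sample_period,
            transient=self.transient,
            mode_labels=self.mode_labels,
        )

    def post_transient(self) -> "TimeSeries4D":
        """Drop the samples flagged as transient (t < transient)."""
        keep = self.time >= self.transient
        return TimeSeries4D(
            data=self.data[keep],
            time=self.time[keep],
            state_labels=self.state_labels,
            region_labels=self.region_labels,
            sample_period=self.sample_period,
            transient=0.0,
            mode_labels=self.mode_labels,
        )

    def __eq__(self, other):
        if not isinstance(other, TimeSeries4D):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.time, other.time)
            and self.state_labels == other.state_labels
            and self.region_labels == other.region_labels
            and self.sample_period == other.sample_period
        )


def write_csv(ts: TimeSeries4D, path) -> None:
    """Columnar text export: time plus one ``state:region`` column per pair."""
    nt, ns, nr, nm = ts.data.shape
    if nm != 1:
        raise ValueError("text export supports single-mode series only")
    flat = ts.data[..., 0].reshape(nt, ns * nr)
    header = ["time"] + [
        f"{s}:{r}" for s in ts.state_labels for r in ts.region_labels
    ]
    meta = f"# sample_period={ts.sample_period!r} transient={ts.transient!r}\n"
    body = np.column_stack([ts.time, flat])
    with open(path, "w") as fh:
        fh.write(meta)
        fh.write(",".join(header) + "\n")
        np.savetxt(fh, body, delimiter=",")


def read_csv(path) -> TimeSeries4D:
    lines = Path(path).read_text().splitlines()
    meta = dict(
        kv.split("=") for kv in lines[0].lstrip("# ").split()
    )
    header = lines[1].split(",")[1:]
    states, regions = [], []
    for col in header:
        s, r = col.split(":", 1)
        if s not in states:
            states.append(s)
        if r not in regions:
            regions.append(r)
    body = np.loadtxt(lines[2:], delimiter=",", ndmin=2)
    time = body[:, 0]
    data = body[:, 1:].reshape(len(time), len(states), len(regions), 1)
    return TimeSeries4D(
        data=data,
        time=time,
        state_labels=states,
        region_labels=regions,
        sample_period=float(meta["sample_period"]),
        transient=float(meta["transient"]),
    )


def write_npz(ts: TimeSeries4D, path) -> None:
    """Self-describing binary container with labeled axes."""
    np.savez(
        path,
        data=ts.data,
        time=ts.time,
        state_labels=np.array(ts.state_labels),
        region_labels=np.array(ts.region_labels),
        mode_labels=np.array(ts.mode_labels),
        sample_period=ts.sample_period,
        transient=ts.transient,
    )


def read_npz(path) -> TimeSeries4D:
    with np.load(path, allow_pickle=False) as z:
        return TimeSeries4D(
            data=z["data"],
            time=z["time"],
            state_labels=[str(s) for s in z["state_labels"]],
            region_labels=[str(r) for r in z["region_labels"]],
            mode_labels=[str(m) for m in z["mode_labels"]],
            sample_period=float(z["sample_period"]),
            transient=float(z["transient"]),
        )
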