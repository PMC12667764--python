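"""Connectomes, conduction delays, weight normalization, synthetic networks.

A connectome couples regions through two square matrices: ``weights``
(streamline-count-like coupling strengths g_ij) and ``tract_lengths``
(fiber distances D_ij in mm).  Conduction delays follow tau_ij = D_ij / v
for a conduction velocity v in mm/ms, discretized to integration steps by
nearest-integer rounding.

Matrix orientation: ``weights[i, j]`` is the connection from source region
``j`` into target region ``i``, matching the afferent sum over j in the
network equation.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import NeuromassError


class ConnectomeError(NeuromassError):
    pass


@dataclass
class Connectome:
    labels: list
    weights: np.ndarray
    tract_lengths: np.ndarray
    parcellation: Optional[dict] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        self.labels = list(self.labels)
        validate_connectome(self)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __eq__(self, other):
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.tract_lengths, other.tract_lengths)
            and self.parcellation == other.parcellation
        )


def validate_connectome(c: Connectome) -> None:
    n = len(c.labels)
    for name, m in (("weights", c.weights), ("tract_lengths", c.tract_lengths)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConnectomeError(f"{name} matrix is not square: shape {m.shape}")
        if m.shape[0] != n:
            raise ConnectomeError(
                f"{name} is {m.shape[0]}x{m.shape[1]} but {n} labels were given"
            )
        neg = np.argwhere(m < 0)
        if neg.size:
            i, j = neg[0]
            raise ConnectomeError(f"negative entry in {name} at (row {i}, col {j})")
    if np.any(np.diag(c.tract_lengths) != 0):
        raise ConnectomeError("tract_lengths must have a zero diagonal")


@dataclass
class DelayMatrix:
    """Inter-regional delays in ms and in integration steps."""

    tau: np.ndarray
    steps: np.ndarray

    @property
    def max_steps(self) -> int:
        return int(self.steps.max()) if self.steps.size else 0

    @property
    def horizon(self) -> int:
        """History length (in steps) a simulator must retain."""
        return self.max_steps + 1


def compute_delays(c: Connectome, v: float, dt: float) -> DelayMatrix:
    """Delays tau_ij = D_ij / v (ms) and steps = round(tau / dt).

    ``v`` is the conduction velocity in mm/ms, ``dt`` the integration step
    in ms; both must be positive.
    """
    if v <= 0:
        raise ValueError(f"conduction velocity must be positive, got {v}")
    if dt <= 0:
        raise ValueError(f"integration step must be positive, got {dt}")
    tau = c.tract_lengths / v
    steps = np.rint(tau / dt).astype(int)
    return DelayMatrix(tau=tau, steps=steps)


def minmax_normalize(W: np.ndarray) -> np.ndarray:
    """Affine rescaling (W - Wmin) / (Wmax - Wmin) onto [0, 1].

    Order-preserving and idempotent on matrices already spanning [0, 1].
    A constant matrix has no defined normalization and raises ValueError.
    """
    W = np.asarray(W, dtype=float)
    lo, hi = W.min(), W.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined for a constant matrix")
    return (W - lo) / (hi - lo)


def synthetic_connectome(
    n: int,
    density: float = 0.3,
    length_scale: float = 100.0,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> Connectome:
    """Generate a random symmetric connectome for testing and examples.

    Off-diagonal connections are present with probability ``density`` and
    carry lognormal weights (a heavy-tailed distribution resembling
    streamline counts); tract lengths are positive wherever weights are
    nonzero, drawn uniformly around ``length_scale`` mm.  Deterministic
    under a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    m = len(iu[0])
    present = rng.random(m) < density
    if not present.any():  # guarantee a connected pair at low density
        present[rng.integers(m)] = True
    w_upper = np.where(present, rng.lognormal(mean=0.0, sigma=1.0, size=m), 0.0)
    l_upper = np.where(present, rng.uniform(0.2, 1.8, size=m) * length_scale, 0.0)
    W = np.zeros((n, n))
    L = np.zeros((n, n))
    W[iu] = w_upper
    L[iu] = l_upper
    W += W.T
    L += L.T
    if labels is None:
        labels = [f"region_{i:02d}" for i in range(n)]
    return Connectome(labels=list(labels), weights=W, tract_lengths=L,
                      parcellation={"atlas": "synthetic", "space": "none"})


def _load_matrix(path: Path) -> np.ndarray:
    text = path.read_text()
    delim = "," if "," in text.splitlines()[0] else None
    try:
        m = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(f"could not parse matrix file {path}: {exc}") from None
    return m


def read_connectome(weights_path, lengths_path, labels_path,
                    parcellation: Optional[dict] = None) -> Connectome:
    """Read a connectome from delimited-text matrices and a label list.

    Accepts CSV or whitespace-delimited matrices; labels one per line.
    Raises :class:`ConnectomeError` on shape mismatches or negative entries.
    """
    W = _load_matrix(Path(weights_path))
    L = _load_matrix(Path(lengths_path))
    labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    return Connectome(labels=labels, weights=W, tract_lengths=L, parcellation=parcellation)


def read_connectome_zip(zip_path, weights_name="weights.csv",
                        lengths_name="tract_lengths.csv",
                        labels_name="labels.txt") -> Connectome:
    """Read the three connectome files bundled in a single zip archive."""
    import io

    with zipfile.ZipFile(zip_path) as zf:
        def load(name):
            with zf.open(name) as fh:
                text = io.TextIOWrapper(fh, encoding="utf-8").read()
            return text

        wtxt, ltxt, labtxt = load(weights_name), load(lengths_name), load(labels_name)
    delim = "," if "," in wtxt.splitlines()[0] else None
    W = np.loadtxt(wtxt.splitlines(), delimiter=delim, ndmin=2)
    L = np.loadtxt(ltxt.splitlines(), delimiter="," if "," in ltxt.splitlines()[0] else None, ndmin=2)
    labels = [ln.strip() for ln in labtxt.splitlines() if ln.strip()]
    return Connectome(labels=labels, weights=W, tract_lengths=L)


def write_connectome(c: Connectome, weights_path, lengths_path, labels_path) -> None:
    np.savetxt(weights_path, c.weights, delimiter=",")
    np.savetxt(lengths_path, c.tract_lengths, delimiter=",")
    Path(labels_path).write_text("\n".join(c.labels) + "\n")
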