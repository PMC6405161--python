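"""Weighted structural connectomes.

A connectome is a square, symmetric, non-negative matrix of white-matter
connection weights (track-count derived, dimensionless) between brain
regions, with a zero diagonal. Diffusion tractography produces undirected
matrices, so asymmetries beyond numerical noise are treated as artifacts
and symmetrized with a warning. All downstream dynamics assume the matrix
has been max-normalized so the strongest connection has weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EdgeIndexError,
    LabelCountError,
    NegativeWeightError,
    NonFiniteWeightError,
    NonSquareMatrixError,
    ValidationError,
    ZeroMatrixError,
)

#: tolerance under which a matrix counts as symmetric (DTI matrices are undirected)
SYMMETRY_TOL = 1e-12


def default_labels(n: int) -> tuple[str, ...]:
    """Region labels ``R000 .. R{n-1}`` used when no sidecar is given."""
    return tuple(f"R{i:03d}" for i in range(n))


@dataclass(frozen=True)
class Connectome:
    """Validated weighted structural connectivity matrix.

    Parameters
    ----------
    weights
        N x N non-negative real matrix; symmetric, zero diagonal.
    labels
        One region name per node.
    normalized
        True if the maximum entry equals 1 (max-normalization applied).
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareMatrixError(
                f"connectivity matrix must be square, got shape {w.shape}"
            )
        bad = ~np.isfinite(w)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise NonFiniteWeightError(
                f"non-finite weight {w[i, j]!r} at entry ({i}, {j})"
            )
        neg = w < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise NegativeWeightError(
                f"negative weight {w[i, j]} at entry ({i}, {j})"
            )
        asym = np.abs(w - w.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            warnings.warn(
                f"matrix asymmetric (max |K - K^T| = {asym:.3g}); "
                "symmetrizing as (K + K^T)/2",
                stacklevel=2,
            )
            w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0):
            warnings.warn("non-zero diagonal entries set to 0", stacklevel=2)
            np.fill_diagonal(w, 0.0)
        labels = tuple(self.labels) if self.labels else default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise LabelCountError(
                f"{len(labels)} labels for {w.shape[0]} regions"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown region label {label!r}") from None

    def degree(self, i: int) -> int:
        """Number of positive-weight links incident to node ``i``."""
        return int(np.count_nonzero(self.weights[i]))


def load_connectome(path: str | Path, labels_path: str | Path | None = None) -> Connectome:
    """Read a delimited square numeric matrix (comma or whitespace).

    Labels come from the optional sidecar (one region name per line, same
    order); otherwise ``R000..`` defaults are used.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"cannot parse {path} as a numeric matrix: {exc}") from exc
    labels: tuple[str, ...] = ()
    if labels_path is not None:
        labels = tuple(
            line.strip() for line in Path(labels_path).read_text().splitlines() if line.strip()
        )
    c = Connectome(w, labels)
    max_w = float(c.weights.max(initial=0.0))
    if max_w == 1.0:
        c = Connectome(c.weights, c.labels, normalized=True)
    return c


def write_connectome(c: Connectome, path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write the matrix in repr round-trip precision, one row per line."""
    lines = [" ".join(repr(float(v)) for v in row) for row in c.weights]
    Path(path).write_text("\n".join(lines) + "\n")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(c.labels) + "\n")


def normalize(c: Connectome) -> Connectome:
    """Divide all weights by the maximum entry so the new maximum is 1.

    Idempotent: a matrix whose maximum is already 1 is returned bit-for-bit
    unchanged (division by 1.0 is exact).
    """
    max_w = float(c.weights.max(initial=0.0))
    if max_w == 0.0:
        raise ZeroMatrixError("all-zero matrix has no scale to normalize by")
    return Connectome(c.weights / max_w, c.labels, normalized=True)


def remove_edge(c: Connectome, i: int, j: int) -> Connectome:
    """Return a copy with the symmetric pair (i, j), (j, i) zeroed.

    Models the virtual ablation of a single white-matter link. Removing an
    already-absent edge is a no-op (idempotent).
    """
    if not (0 <= i < c.n and 0 <= j < c.n):
        raise EdgeIndexError(f"edge ({i}, {j}) out of range for N={c.n}")
    if i == j:
        raise EdgeIndexError(f"self-edge ({i}, {i}) does not exist")
    w = c.weights.copy()
    w[i, j] = 0.0
    w[j, i] = 0.0
    still_normalized = c.normalized and float(w.max(initial=0.0)) == 1.0
    return Connectome(w, c.labels, normalized=still_normalized)


def average_connectomes(cs: Sequence[Connectome] | Iterable[Connectome]) -> Connectome:
    """Element-wise arithmetic mean of several connectomes, re-normalized.

    The mean is re-normalized to max 1 afterwards so downstream dynamics see
    the same coupling scale as individual subjects. Labels are taken from
    the first input.
    """
    cs = list(cs)
    if not cs:
        raise ValidationError("cannot average an empty list of connectomes")
    n = cs[0].n
    for k, c in enumerate(cs):
        if c.n != n:
            raise ValidationError(
                f"size mismatch: connectome 0 has N={n}, connectome {k} has N={c.n}"
            )
    mean = np.mean([c.weights for c in cs], axis=0)
    return normalize(Connectome(mean, cs[0].labels))
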