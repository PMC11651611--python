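"""Structural connectome I/O, normalisation, delays, and synthetic generation.

A :class:`Connectome` couples a non-negative symmetric weight matrix ``w_ij``
(dimensionless connection strengths between cortical regions) with a tract
length matrix ``d_ij`` in millimetres. Conduction delays follow as
``T_ij = d_ij / v`` for a uniform axonal conduction speed ``v`` (m/s).

Weight matrices are row-normalised before simulation so afferent strengths
per region sum to unity; normalisation is always an explicit call, never
applied silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "ConnectomeValidationError",
    "ShapeMismatchError",
    "NegativeEntryError",
    "NonFiniteEntryError",
    "ZeroRowError",
    "load_connectome",
    "save_connectome_hdf5",
    "load_connectome_hdf5",
    "row_normalize",
    "delays_from_distances",
    "generate_synthetic_connectome",
]


class ConnectomeValidationError(ValueError):
    """Base class for structural-data validation failures."""


class ShapeMismatchError(ConnectomeValidationError):
    pass


class NegativeEntryError(ConnectomeValidationError):
    pass


class NonFiniteEntryError(ConnectomeValidationError):
    pass


class ZeroRowError(ConnectomeValidationError):
    pass


@dataclass(frozen=True)
class Connectome:
    """Weights, distances and region metadata for an N-region network.

    weights: N x N non-negative, symmetric (before row normalisation), zero
    diagonal. distances: N x N in mm, symmetric, zero diagonal, positive
    wherever a weight is positive. hemisphere: boolean, True for right.
    """

    weights: np.ndarray
    distances: np.ndarray
    labels: tuple[str, ...] = ()
    hemisphere: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "distances", d)
        _validate(w, d)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"region_{i}" for i in range(w.shape[0]))
            )
        if len(self.labels) != w.shape[0]:
            raise ShapeMismatchError("label count does not match matrix size")
        if self.hemisphere is not None:
            hemi = np.asarray(self.hemisphere, dtype=bool)
            if hemi.shape != (w.shape[0],):
                raise ShapeMismatchError("hemisphere flags do not match matrix size")
            object.__setattr__(self, "hemisphere", hemi)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def is_row_normalized(self) -> bool:
        return bool(np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-12, rtol=0.0))


def _validate(w: np.ndarray, d: np.ndarray) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeMismatchError(f"weights must be square, got shape {w.shape}")
    if d.shape != w.shape:
        raise ShapeMismatchError(
            f"distance matrix shape {d.shape} does not match weights {w.shape}"
        )
    for name, m in (("weights", w), ("distances", d)):
        if not np.all(np.isfinite(m)):
            raise NonFiniteEntryError(f"{name} contain NaN or infinite entries")
        if np.any(m < 0):
            raise NegativeEntryError(f"{name} contain negative entries")
    if np.any((w > 0) & (d <= 0) & ~np.eye(w.shape[0], dtype=bool)):
        raise ConnectomeValidationError(
            "positive weight with non-positive distance off the diagonal"
        )


def _read_matrix_csv(path: str | Path) -> np.ndarray:
    """Dense numeric CSV, no header by default; header+index stripped if present."""
    df = pd.read_csv(path, header=None)
    # Heuristic: a text header/index shows up as object-dtype first row/column.
    if df.iloc[0].apply(lambda x: isinstance(x, str) and not _is_number(x)).any():
        df = pd.read_csv(path, header=0, index_col=0)
    return df.to_numpy(dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def load_connectome(
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
) -> Connectome:
    """Load weights/distances from dense CSV matrices and validate them.

    Small asymmetries are removed by (A + A^T)/2; a warning is emitted when
    the maximum asymmetry exceeds 1e-8.
    """
    w = _read_matrix_csv(weights_path)
    d = _read_matrix_csv(distances_path)
    if w.shape != d.shape:
        raise ShapeMismatchError(
            f"weights {w.shape} and distances {d.shape} differ in shape"
        )
    for name, m in (("weights", w), ("distances", d)):
        if not np.all(np.isfinite(m)):
            raise NonFiniteEntryError(f"{name} file contains NaN or infinite entries")
        if np.any(m < 0):
            raise NegativeEntryError(f"{name} file contains negative entries")
    w = _symmetrize(w, "weights")
    d = _symmetrize(d, "distances")
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(d, 0.0)
    labels: tuple[str, ...] = ()
    if labels_path is not None:
        labels = tuple(
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        )
    return Connectome(weights=w, distances=d, labels=labels)


def _symmetrize(m: np.ndarray, name: str) -> np.ndarray:
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > 1e-8:
        warnings.warn(
            f"{name} matrix asymmetric (max |A - A^T| = {asym:.3g}); "
            "symmetrised as (A + A^T)/2",
            stacklevel=3,
        )
    return 0.5 * (m + m.T)


def row_normalize(c: Connectome) -> Connectome:
    """Scale each row of the weights to sum to one (afferent normalisation).

    Idempotent; preserves the zero pattern. A row summing to zero is an
    error: every region must receive input.
    """
    sums = c.weights.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ZeroRowError(
            f"rows with zero afferent weight sum at node indices {bad.tolist()} "
            f"(labels: {[c.labels[i] for i in bad]})"
        )
    return replace(c, weights=c.weights / sums[:, None])


def delays_from_distances(c: Connectome, speed: float) -> np.ndarray:
    """Conduction delays T_ij = d_ij / v, in seconds (distances in mm)."""
    if speed <= 0:
        raise ValueError("conduction speed must be strictly positive")
    T = (c.distances * 1e-3) / speed
    np.fill_diagonal(T, 0.0)
    return T


def generate_synthetic_connectome(
    n_regions: int = 68,
    seed: int = 0,
    intra_hemi_density: float = 0.65,
    decay_length: float = 60.0,
) -> Connectome:
    """Generate a two-hemisphere synthetic structural connectome.

    Emulates the statistical features of diffusion-MRI connectomes at
    Desikan-Killiany scale: symmetric non-negative weights with log-normal
    magnitudes damped by exp(-d/decay_length); denser intra- than
    inter-hemispheric connectivity; region centroids drawn as two mirrored
    3-D point clouds scaled so distances span roughly 10-170 mm, compatible
    with conduction delays of a few to tens of ms at 12 m/s. Deterministic
    given the seed, and always connected as a graph.

    Weights are returned un-normalised; call :func:`row_normalize` before
    simulation.
    """
    if n_regions < 4:
        raise ValueError("n_regions must be at least 4")
    if n_regions % 2:
        raise ValueError("n_regions must be even (two hemispheres)")
    if not 0 < intra_hemi_density <= 1:
        raise ValueError("intra_hemi_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    half = n_regions // 2

    # Mirrored centroid clouds: left hemisphere x < 0, right x > 0.
    left = rng.normal(size=(half, 3)) * np.array([18.0, 35.0, 25.0])
    left[:, 0] = -np.abs(left[:, 0]) - 8.0
    right = left * np.array([-1.0, 1.0, 1.0]) + rng.normal(
        scale=4.0, size=(half, 3)
    )
    pts = np.vstack([left, right])
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    # Rescale off-diagonal distances into roughly the 10-170 mm range.
    off = ~np.eye(n_regions, dtype=bool)
    lo, hi = d[off].min(), d[off].max()
    d = np.where(off, 10.0 + (d - lo) * (160.0 / max(hi - lo, 1e-12)), 0.0)
    d = 0.5 * (d + d.T)

    hemi = np.zeros(n_regions, dtype=bool)
    hemi[half:] = True
    intra = hemi[:, None] == hemi[None, :]
    density = np.where(intra, intra_hemi_density, intra_hemi_density / 3.0)
    iu = np.triu_indices(n_regions, k=1)
    mask = np.zeros((n_regions, n_regions), dtype=bool)
    mask[iu] = rng.random(iu[0].size) < density[iu]
    mask |= mask.T

    mag = np.zeros((n_regions, n_regions))
    mag[iu] = rng.lognormal(mean=0.0, sigma=0.8, size=iu[0].size)
    mag += mag.T
    w = np.where(mask, mag * np.exp(-d / decay_length), 0.0)
    np.fill_diagonal(w, 0.0)

    # Guarantee graph connectivity by bridging components along shortest gaps.
    g = nx.from_numpy_array(w)
    comps = list(nx.connected_components(g))
    while len(comps) > 1:
        a = np.fromiter(comps[0], int)
        b = np.fromiter(comps[1], int)
        sub = d[np.ix_(a, b)]
        ia, ib = np.unravel_index(np.argmin(sub), sub.shape)
        i, j = a[ia], b[ib]
        w[i, j] = w[j, i] = np.exp(-d[i, j] / decay_length)
        g.add_edge(i, j)
        comps = list(nx.connected_components(g))

    labels = tuple(
        f"{'rh' if hemi[i] else 'lh'}_region_{i % half:02d}" for i in range(n_regions)
    )
    return Connectome(weights=w, distances=d, labels=labels, hemisphere=hemi)


def save_connectome_hdf5(c: Connectome, path: str | Path) -> None:
    """Persist a connectome bundle as an HDF5 group {weights, distances, labels, meta}."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("connectome")
        g.create_dataset("weights", data=c.weights)
        g.create_dataset("distances", data=c.distances)
        g.create_dataset(
            "labels", data=np.array([s.encode() for s in c.labels])
        )
        if c.hemisphere is not None:
            g.create_dataset("hemisphere", data=c.hemisphere.astype(np.uint8))
        g.attrs["n_regions"] = c.n_regions


def load_connectome_hdf5(path: str | Path) -> Connectome:
    with h5py.File(path, "r") as fh:
        g = fh["connectome"]
        labels = tuple(s.decode() for s in g["labels"][()])
        hemi = g["hemisphere"][()].astype(bool) if "hemisphere" in g else None
        return Connectome(
            weights=g["weights"][()],
            distances=g["distances"][()],
            labels=labels,
            hemisphere=hemi,
        )


def save_connectome_csv(
    c: Connectome,
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write the dense CSV representation read back by :func:`load_connectome`."""
    np.savetxt(weights_path, c.weights, delimiter=",")
    np.savetxt(distances_path, c.distances, delimiter=",")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(c.labels) + "\n")
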