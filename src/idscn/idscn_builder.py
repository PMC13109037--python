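"""Individualized structural covariance networks from z-score rows.

Each subject's network is a similarity map over cortical regions: the edge
weight between regions i and j measures how concordantly the two regions
deviate from the healthy-control reference, via a kernel of the z-score
difference |z_i - z_j|. Weights lie in (0, 1] and equal 1 exactly when the
two deviations coincide. Weighted matrices are thresholded to a fixed edge
density K (keeping the m largest weights) and binarized before any graph
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphometry_prep import ZScoreMatrix

#: Similarity kernels of the absolute z-difference d at scale c. All map
#: d = 0 to 1 and decrease monotonically, so the similarity semantics and
#: the induced edge ranking are interchangeable across the family.
KERNELS = {
    "gaussian": lambda d, c: np.exp(-(d * d) / (2.0 * c * c)),
    "laplacian": lambda d, c: np.exp(-d / c),
    "inverse": lambda d, c: 1.0 / (1.0 + d / c),
}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so 0.215 -> 0.22 at 2 decimals)."""
    factor = 10.0**decimals
    scaled = round(x * factor, 9)  # strip float representation fuzz first
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


@dataclass
class IDSCNMatrix:
    """Symmetric weighted similarity matrix for one subject."""

    weights: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if np.any(off <= 0) or np.any(off > 1):
            raise ValueError("off-diagonal weights must lie in (0, 1]")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class DensityGrid:
    """Strictly increasing densities in (0, 0.5]."""

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(5, 31) / 100.0, 2)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("density grid must be a non-empty 1-d sequence")
        if np.any(np.diff(v) <= 0):
            raise ValueError("density grid must be strictly increasing")
        if v[0] <= 0 or v[-1] > 0.5:
            raise ValueError("densities must lie in (0, 0.5]")
        self.values = v

    @classmethod
    def from_string(cls, spec: str) -> "DensityGrid":
        """Parse ``low:high:step``, e.g. ``0.05:0.30:0.01`` (inclusive ends)."""
        try:
            low, high, step = (float(part) for part in spec.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse density grid spec {spec!r}") from exc
        n = int(round((high - low) / step)) + 1
        return cls(np.round(low + step * np.arange(n), 10))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class BinaryNetwork:
    """Undirected 0/1 adjacency at a fixed density, no self-loops."""

    adjacency: np.ndarray
    density: float
    n_edges: int = -1

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        m = int(a.sum()) // 2
        if self.n_edges < 0:
            self.n_edges = m
        elif self.n_edges != m:
            raise ValueError(f"edge count mismatch: declared {self.n_edges}, found {m}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def joint_variation_weights(
    z_row: np.ndarray,
    kernel: str = "gaussian",
    scale: float = 1.0,
    subject_id: str = "",
) -> IDSCNMatrix:
    """Edge weights w_ij = kernel(|z_i - z_j|; scale), zero diagonal.

    The default Gaussian kernel gives w_ij = exp(-(z_i - z_j)^2 / (2 c^2)).
    Adding a constant to every z leaves the matrix unchanged (the kernel sees
    only pairwise differences).
    """
    z = np.asarray(z_row, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    if scale <= 0:
        raise ValueError("kernel scale must be > 0")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    d = np.abs(z[:, None] - z[None, :])
    w = KERNELS[kernel](d, scale)
    np.fill_diagonal(w, 0.0)
    return IDSCNMatrix(weights=w, subject_id=subject_id)


def ranked_edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j).

    Returns (rows, cols) index arrays; the deterministic tie-break makes
    thresholded networks reproducible and nested across densities.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    # np.lexsort sorts by the last key first: primary -w, then i, then j
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_binarize(idscn: IDSCNMatrix, density: float) -> BinaryNetwork:
    """Keep the m = round(K n(n-1)/2) strongest edges and binarize."""
    if not 0 < density <= 0.5:
        raise ValueError("density must lie in (0, 0.5]")
    n = idscn.n_regions
    max_edges = n * (n - 1) // 2
    m = int(round_half_away(density * max_edges))
    if m == 0:
        raise ValueError(f"density {density} keeps zero edges for n={n}")
    rows, cols = ranked_edge_order(idscn.weights)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[rows[:m], cols[:m]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, density=float(density), n_edges=m)


def build_all_networks(
    zmatrix: ZScoreMatrix,
    grid: DensityGrid,
    kernel: str = "gaussian",
    scale: float = 1.0,
) -> dict[str, list[BinaryNetwork]]:
    """Binarized networks for every subject at every grid density.

    Returns ``{subject_id: [BinaryNetwork, ...]}`` with the list aligned to
    ``grid.values``. Fully deterministic.
    """
    out: dict[str, list[BinaryNetwork]] = {}
    for subject_id, row in zmatrix.z.iterrows():
        idscn = joint_variation_weights(
            row.to_numpy(), kernel=kernel, scale=scale, subject_id=str(subject_id)
        )
        out[str(subject_id)] = [threshold_binarize(idscn, k) for k in grid]
    return out
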