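"""Graph container, normalized Laplacian, spectral decomposition and heat kernel.

The normalized graph Laplacian of a simple undirected weighted graph with
adjacency matrix ``A`` and strength (weighted degree) matrix ``D`` is

    L = D^{-1/2} (D - A) D^{-1/2},

with the convention ``D_ii^{-1/2} = 0`` for zero-strength nodes, so an
isolated node contributes an all-zero row and column (and therefore retains
its heat: ``h(t)_ii = 1`` for all t).  Its eigenvalues lie in ``[0, 2]`` and
the multiplicity of the zero eigenvalue counts the connected components that
carry at least one edge.

Diffusion on the graph is governed by the heat equation ``dh/dt = -L h`` with
``h(0) = I``, whose solution is the heat kernel

    h(t) = exp(-t L) = sum_i exp(-lambda_i t) v_i v_i^T.

``h(t)_ij`` is the amount of heat transferred from node i to node j after
time t; it is the quantity the adaptive rewiring rule ranks candidate edges
by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedGraph",
    "SpectralDecomposition",
    "HeatKernel",
    "normalized_laplacian",
    "spectral_decomposition",
    "heat_kernel",
    "heat_kernel_matrix",
    "fiedler_order",
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "write_edge_list",
]

_SYM_TOL = 1e-8


class InvalidGraphError(ValueError):
    """Raised when a matrix does not describe a simple nonnegative graph."""


@dataclass
class WeightedGraph:
    """Simple undirected graph with nonnegative edge weights.

    The adjacency matrix is symmetric with a zero diagonal; an entry
    ``A[i, j] > 0`` is the weight of edge (i, j) and ``A[i, j] == 0`` means
    the nodes are not adjacent.  Binary graphs carry only weights in {0, 1}.
    """

    adjacency: np.ndarray
    is_binary: bool = field(default=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidGraphError("adjacency must be a square matrix")
        if not np.allclose(A, A.T, atol=_SYM_TOL):
            raise InvalidGraphError("adjacency must be symmetric")
        if np.any(A < 0):
            raise InvalidGraphError("edge weights must be nonnegative")
        if np.any(np.diagonal(A) != 0):
            raise InvalidGraphError("diagonal must be zero (no self loops)")
        self.adjacency = A
        if self.is_binary and not np.all(np.isin(A, (0.0, 1.0))):
            raise InvalidGraphError("binary graph must have weights in {0, 1}")

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def degrees(self) -> np.ndarray:
        """Number of incident edges per node."""
        return (self.adjacency > 0).sum(axis=1)

    @property
    def strengths(self) -> np.ndarray:
        """Sum of incident edge weights per node (equals degree when binary)."""
        return self.adjacency.sum(axis=1)

    @property
    def weights(self) -> np.ndarray:
        """The multiset of edge weights (upper triangle, positive entries)."""
        iu = np.triu_indices(self.node_count, k=1)
        w = self.adjacency[iu]
        return w[w > 0]

    def copy(self) -> "WeightedGraph":
        return WeightedGraph(self.adjacency.copy(), is_binary=self.is_binary)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenvalues (ascending, in [0, 2]) and orthonormal eigenvectors of L."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def fiedler_value(self) -> float:
        """Smallest nonzero eigenvalue."""
        idx = _first_nonzero_index(self.eigenvalues)
        return float(self.eigenvalues[idx])

    @property
    def fiedler_vector(self) -> np.ndarray:
        """Eigenvector of the smallest nonzero eigenvalue."""
        idx = _first_nonzero_index(self.eigenvalues)
        return self.eigenvectors[:, idx]


@dataclass(frozen=True)
class HeatKernel:
    """Heat kernel h(t): entry (i, j) is heat moved from node i to j by time t."""

    matrix: np.ndarray
    time: float


def normalized_laplacian(g: WeightedGraph) -> np.ndarray:
    """Normalized graph Laplacian ``D^{-1/2}(D - A)D^{-1/2}``.

    Zero-strength (isolated) nodes get an all-zero row and column, following
    the matrix-product definition with ``D_ii^{-1/2} = 0``.
    """
    A = g.adjacency
    s = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(s > 0, 1.0 / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    L = -(A * d_isqrt[:, None]) * d_isqrt[None, :]
    np.fill_diagonal(L, np.where(s > 0, 1.0, 0.0))
    return L


def _laplacian_from_adjacency(A: np.ndarray) -> np.ndarray:
    # fast path used in the rewiring inner loop; skips invariant checks
    s = A.sum(axis=1)
    d_isqrt = np.where(s > 0, 1.0 / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    L = -(A * d_isqrt[:, None]) * d_isqrt[None, :]
    np.fill_diagonal(L, np.where(s > 0, 1.0, 0.0))
    return L


def spectral_decomposition(L: np.ndarray) -> SpectralDecomposition:
    """Eigendecomposition of a symmetric Laplacian, eigenvalues ascending.

    Tiny negative eigenvalues are clamped to zero.  Each eigenvector's sign is
    fixed so its largest-magnitude entry is positive, removing the arbitrary
    global sign.
    """
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=_SYM_TOL):
        raise ValueError("Laplacian must be symmetric")
    lam, V = np.linalg.eigh(L)
    lam = np.where(np.abs(lam) < _SYM_TOL, 0.0, lam)
    # sign convention: largest-|.| entry of each eigenvector is positive
    anchor = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[anchor, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return SpectralDecomposition(eigenvalues=lam, eigenvectors=V * signs)


def heat_kernel(decomp: SpectralDecomposition, t: float) -> HeatKernel:
    """Heat kernel ``h(t) = V exp(-t Lambda) V^T`` from a spectral decomposition."""
    if t < 0:
        raise ValueError("diffusion time must be nonnegative")
    lam = np.clip(decomp.eigenvalues, 0.0, None)
    V = decomp.eigenvectors
    H = (V * np.exp(-lam * t)) @ V.T
    H = (H + H.T) / 2.0
    return HeatKernel(matrix=H, time=float(t))


def heat_kernel_matrix(g: WeightedGraph, t: float) -> np.ndarray:
    """Convenience: h(t) recomputed from the graph's current adjacency."""
    return heat_kernel(spectral_decomposition(normalized_laplacian(g)), t).matrix


def _first_nonzero_index(eigenvalues: np.ndarray, tol: float = _SYM_TOL) -> int:
    idx = np.flatnonzero(eigenvalues > tol)
    if idx.size == 0:
        raise ValueError("graph has no edges: Fiedler vector undefined")
    return int(idx[0])


def fiedler_order(decomp: SpectralDecomposition) -> np.ndarray:
    """Node permutation sorting by ascending Fiedler-vector entry.

    Sorting the adjacency matrix rows/columns by this permutation makes
    community block structure visible.  The permutation is only defined up to
    a global reversal (eigenvector sign ambiguity).
    """
    return np.argsort(decomp.fiedler_vector, kind="stable")


# ---------------------------------------------------------------------------
# plain-text I/O: dense matrices and weighted edge lists


def read_adjacency(path, is_binary: bool | None = None) -> WeightedGraph:
    """Read a dense whitespace- or comma-delimited adjacency matrix."""
    with open(path) as fh:
        first = fh.read(4096)
    delimiter = "," if "," in first.splitlines()[0] else None
    A = np.loadtxt(path, delimiter=delimiter)
    if is_binary is None:
        is_binary = bool(np.all(np.isin(A, (0.0, 1.0))))
    return WeightedGraph(A, is_binary=is_binary)


def write_adjacency(path, g: WeightedGraph) -> None:
    np.savetxt(path, g.adjacency, fmt="%.10g")


def read_edge_list(path, node_count: int | None = None) -> WeightedGraph:
    """Read ``i j weight`` rows (0-based node indices) into a graph."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 2:  # unweighted: implicit weight 1
        data = np.column_stack([data, np.ones(len(data))])
    i, j, w = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2]
    n = node_count if node_count is not None else int(max(i.max(), j.max())) + 1
    A = np.zeros((n, n))
    A[i, j] = w
    A[j, i] = w
    return WeightedGraph(A, is_binary=bool(np.all(np.isin(A, (0.0, 1.0)))))


def write_edge_list(path, g: WeightedGraph) -> None:
    i, j = np.triu_indices(g.node_count, k=1)
    mask = g.adjacency[i, j] > 0
    rows = np.column_stack([i[mask], j[mask], g.adjacency[i, j][mask]])
    np.savetxt(path, rows, fmt=["%d", "%d", "%.10g"])
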