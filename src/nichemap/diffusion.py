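"""Diffusion variables from a kNN similarity graph over trait profiles.

Genomes are compared by Euclidean distance in binary trait space. A
k-nearest-neighbor graph is built with weights decreasing in distance,
union-symmetrized, and the row-normalized graph Laplacian L = I - D^-1 W
is formed. Eigenvectors of L are the diffusion variables: the eigenvector
of the smallest non-zero eigenvalue is variable 1 (the most important
axis of metabolic variation), the next smallest is variable 2, and so on.
Each variable assigns every genome a real coordinate entry; genomes with
extreme entries along a variable form candidate ecological strategy sets.

Eigenpairs are computed through the symmetric conjugate
L_sym = I - D^-1/2 W D^-1/2 and back-transformed (v = D^-1/2 u), which
keeps the spectrum real and the solver stable even though L itself is
not symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, squareform
from sklearn.base import BaseEstimator

from .trait_matrix import TraitMatrix

__all__ = [
    "DiffusionConfig",
    "NeighborGraph",
    "DiffusionResult",
    "DiffusionMap",
    "knn_graph",
    "row_normalized_laplacian",
    "diffusion_eigs",
    "localization_score",
    "diffusion_distance",
    "extremal_taxa",
]

TOL = 1e-8


@dataclass(frozen=True)
class DiffusionConfig:
    """Settings for the diffusion map.

    k : neighbor count for the kNN graph (default 10).
    n_variables : number m of non-trivial variables to retain.
    weight_mode : "inverse_distance" (w = 1/d) or "gaussian"
        (w = exp(-d^2/sigma^2), sigma = median kNN distance).
    allow_disconnected : keep near-zero eigenvectors of a disconnected
        graph instead of erroring (they indicate components, not
        strategies).
    """

    k: int = 10
    n_variables: int = 10
    weight_mode: str = "inverse_distance"
    allow_disconnected: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")
        if self.weight_mode not in ("inverse_distance", "gaussian"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class NeighborGraph:
    """Union-symmetrized weighted kNN graph over genomes."""

    node_ids: list
    weights: np.ndarray  # (N, N) symmetric, nonnegative, zero diagonal

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.node_ids),) * 2:
            raise ValueError("weights shape mismatch")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = W


@dataclass
class DiffusionResult:
    """Eigenvalues and diffusion variables of the row-normalized Laplacian.

    eigenvalues : ascending (m+1,) array; the first is the trivial ~0.
    variables : (N, m) array; column l-1 is variable l (unit norm, sign
        fixed so the largest-magnitude entry is negative).
    localization : (m,) inverse participation ratios, sum(v^4).
    """

    genome_ids: list
    eigenvalues: np.ndarray
    variables: np.ndarray
    localization: np.ndarray

    @property
    def n_variables(self) -> int:
        return self.variables.shape[1]

    def variable(self, index: int) -> np.ndarray:
        """Entries of variable ``index`` (1-based, ascending eigenvalue)."""
        if not 1 <= index <= self.n_variables:
            raise IndexError(f"variable_index must be in [1, {self.n_variables}]")
        return self.variables[:, index - 1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"variable_{l}" for l in range(1, self.n_variables + 1)]
        return pd.DataFrame(
            self.variables, index=pd.Index(self.genome_ids, name="genome_id"),
            columns=cols,
        )


def knn_graph(T: TraitMatrix, config: DiffusionConfig) -> NeighborGraph:
    """Build the union-symmetrized kNN similarity graph of trait rows.

    Each genome's k nearest rows (Euclidean) receive a positive weight;
    the directed relation is symmetrized by the elementwise maximum, so
    every node keeps at least k positive-weight neighbors. Distance ties
    are broken by input row order (stable sort). Duplicate rows (zero
    distance) are rejected: their weight would be infinite — merge
    duplicates first and re-expand afterwards.
    """
    X = np.asarray(T.values, dtype=float)
    N = X.shape[0]
    if config.k >= N:
        raise ValueError(f"k={config.k} must be < number of genomes ({N})")
    D = cdist(X, X, metric="euclidean")
    off = ~np.eye(N, dtype=bool)
    if np.any(D[off] == 0):
        i, j = np.argwhere((D == 0) & off)[0]
        raise ValueError(
            f"duplicate trait rows (e.g. {T.genome_ids[i]!r} == "
            f"{T.genome_ids[j]!r}); deduplicate before mapping"
        )
    Dq = D.copy()
    np.fill_diagonal(Dq, np.inf)
    nbr = np.argsort(Dq, axis=1, kind="stable")[:, : config.k]
    knn_d = np.take_along_axis(Dq, nbr, axis=1)
    if config.weight_mode == "inverse_distance":
        knn_w = 1.0 / knn_d
    else:
        sigma = np.median(knn_d)
        knn_w = np.exp(-(knn_d**2) / sigma**2)
    W = np.zeros((N, N))
    rows = np.repeat(np.arange(N), config.k)
    W[rows, nbr.ravel()] = knn_w.ravel()
    W = np.maximum(W, W.T)
    return NeighborGraph(list(T.genome_ids), W)


def row_normalized_laplacian(G: NeighborGraph) -> np.ndarray:
    """L = I - D^-1 W with D = diag(row sums); every row of L sums to 0."""
    W = G.weights
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        isolated = [G.node_ids[i] for i in np.where(deg <= 0)[0]]
        raise ValueError(f"isolated node(s) with zero degree: {isolated}")
    return np.eye(len(deg)) - W / deg[:, None]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # largest-|entry| made negative; first occurrence breaks ties
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] > 0 else v


def diffusion_eigs(G: NeighborGraph, config: DiffusionConfig) -> DiffusionResult:
    """Smallest m+1 eigenpairs of the row-normalized Laplacian.

    Solved on the symmetric conjugate L_sym = I - D^-1/2 W D^-1/2 and
    back-transformed; the single exact-zero pair (constant eigenvector)
    is dropped, the remaining variables are ordered by ascending
    eigenvalue, unit-normalized, and sign-fixed.
    """
    W = G.weights
    N = W.shape[0]
    m = config.n_variables
    if m > N - 2:
        raise ValueError(f"n_variables={m} must be <= N-2 = {N - 2}")
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("graph has isolated nodes")
    dinv_sqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(N) - (dinv_sqrt[:, None] * W) * dinv_sqrt[None, :]
    L_sym = 0.5 * (L_sym + L_sym.T)
    vals, vecs = eigh(L_sym, subset_by_index=[0, m])
    if vals[1] < TOL and not config.allow_disconnected:
        raise ValueError(
            "graph disconnected (repeated zero eigenvalue); increase k or "
            "set allow_disconnected=True"
        )
    variables = dinv_sqrt[:, None] * vecs[:, 1:]
    variables /= np.linalg.norm(variables, axis=0, keepdims=True)
    for l in range(m):
        variables[:, l] = _fix_sign(variables[:, l])
    ipr = np.sum(variables**4, axis=0)
    return DiffusionResult(list(G.node_ids), vals, variables, ipr)


def localization_score(v: np.ndarray) -> float:
    """Inverse participation ratio sum(v_i^4) of a unit-norm variable.

    Ranges over (1/N, 1]; a delta vector scores 1, a flat vector 1/N.
    High scores mark 'localized' variables whose weight concentrates on
    a small genome cluster with unique capabilities.
    """
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero vector has no localization score")
    v = v / nrm
    return float(np.sum(v**4))


def diffusion_distance(R: DiffusionResult, weighting: str = "flat") -> np.ndarray:
    """Pairwise genome distances in diffusion space.

    "flat": Euclidean over the retained variable entries.
    "inverse_eigenvalue": entries of variable l scaled by 1/lambda_l first,
    emphasizing slow diffusive modes.
    """
    if R.n_variables < 1:
        raise ValueError("need at least one variable")
    coords = R.variables
    if weighting == "inverse_eigenvalue":
        coords = coords / R.eigenvalues[1:][None, :]
    elif weighting != "flat":
        raise ValueError(f"unknown weighting {weighting!r}")
    D = cdist(coords, coords, metric="euclidean")
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def extremal_taxa(R: DiffusionResult, variable_index: int, n: int = 10):
    """The n most-negative and n most-positive genomes along a variable.

    Returns (negative_ids ascending by entry, positive_ids descending);
    entry ties are broken by lexicographic genome_id.
    """
    v = R.variable(variable_index)
    N = len(v)
    if n > N / 2:
        raise ValueError(f"n={n} exceeds N/2 = {N / 2}")
    order_neg = sorted(range(N), key=lambda i: (v[i], R.genome_ids[i]))
    order_pos = sorted(range(N), key=lambda i: (-v[i], R.genome_ids[i]))
    neg = [R.genome_ids[i] for i in order_neg[:n]]
    pos = [R.genome_ids[i] for i in order_pos[:n]]
    return neg, pos


class DiffusionMap(BaseEstimator):
    """Diffusion-map embedding of binary trait profiles.

    scikit-learn-style transformer (in the mold of
    :class:`~sklearn.manifold.SpectralEmbedding`: spectral embeddings have
    no out-of-sample extension, so use :meth:`fit_transform`).

    Parameters
    ----------
    k : int, default=10
        Neighbors in the similarity graph.
    n_variables : int, default=10
        Number of non-trivial diffusion variables to retain.
    weight_mode : {"inverse_distance", "gaussian"}, default="inverse_distance"
    allow_disconnected : bool, default=False

    Attributes
    ----------
    embedding_ : ndarray of shape (n_genomes, n_variables)
        Variable entries, columns ordered by ascending eigenvalue.
    eigenvalues_ : ndarray of shape (n_variables + 1,)
        Ascending Laplacian eigenvalues including the trivial zero.
    localization_ : ndarray of shape (n_variables,)
        Inverse participation ratio of each variable.
    genome_ids_ : list of str
    graph_ : NeighborGraph
    result_ : DiffusionResult

    Examples
    --------
    >>> from nichemap.synthetic import make_clustered_traits, ClusterSpec
    >>> T, labels = make_clustered_traits(ClusterSpec(
    ...     n_core_traits=30, clusters=[(10, 15), (10, 15)],
    ...     n_background_genomes=10, flip_prob=0.02, seed=0,
    ...     force_unique=True))
    >>> coords = DiffusionMap(k=5, n_variables=3).fit_transform(T)
    >>> coords.shape
    (30, 3)
    """

    def __init__(self, k=10, n_variables=10, weight_mode="inverse_distance",
                 allow_disconnected=False):
        self.k = k
        self.n_variables = n_variables
        self.weight_mode = weight_mode
        self.allow_disconnected = allow_disconnected

    def _config(self) -> DiffusionConfig:
        return DiffusionConfig(
            k=self.k, n_variables=self.n_variables,
            weight_mode=self.weight_mode,
            allow_disconnected=self.allow_disconnected,
        )

    def fit(self, X, y=None):
        """Compute the embedding of X (TraitMatrix, DataFrame, or array)."""
        T = self._as_trait_matrix(X)
        config = self._config()
        self.graph_ = knn_graph(T, config)
        self.result_ = diffusion_eigs(self.graph_, config)
        self.genome_ids_ = self.result_.genome_ids
        self.eigenvalues_ = self.result_.eigenvalues
        self.embedding_ = self.result_.variables
        self.localization_ = self.result_.localization
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    @staticmethod
    def _as_trait_matrix(X) -> TraitMatrix:
        if isinstance(X, TraitMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return TraitMatrix(
                list(X.index.astype(str)), list(X.columns.astype(str)),
                X.to_numpy(),
            )
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return TraitMatrix(
            [f"g{i}" for i in range(X.shape[0])],
            [f"t{j}" for j in range(X.shape[1])], X,
        )

    def condensed_distances(self, weighting: str = "flat") -> np.ndarray:
        """Condensed upper-triangle diffusion distances of the fitted genomes."""
        return squareform(diffusion_distance(self.result_, weighting), checks=False)
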