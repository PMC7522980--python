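"""Phylogeny vs metabolism: cophenetic distances and the Mantel test.

A weak positive association between diffusion-space distances and
cophenetic (patristic) tree distances is expected — related taxa deploy
similar metabolic strategies on average — but individual variables can
cut across the phylogeny, reflecting convergence or horizontal transfer.
The Mantel permutation test quantifies that association.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = [
    "MantelResult",
    "parse_newick",
    "read_newick",
    "cophenetic_matrix",
    "mantel",
    "align_ids",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_items: int


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def cophenetic_matrix(tree: dendropy.Tree, leaf_order) -> np.ndarray:
    """Patristic distances: summed branch lengths between leaf pairs.

    Rows/columns follow ``leaf_order``; unknown labels raise.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [l for l in leaf_order if l not in taxa]
    if missing:
        raise KeyError(f"leaf label(s) not in tree: {missing}")
    n = len(leaf_order)
    D = np.zeros((n, n))
    for i, a in enumerate(leaf_order):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[leaf_order[j]])
            D[i, j] = D[j, i] = d
    return D


def align_ids(ids1, ids2):
    """Shared identifiers, in ids1 order; errors on any mismatch.

    Silent subsetting is forbidden: both unmatched directions are named.
    """
    s1, s2 = set(ids1), set(ids2)
    only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
    if only1 or only2:
        raise ValueError(
            f"identifier mismatch: only in first = {only1[:10]}, "
            f"only in second = {only2[:10]}"
        )
    return list(ids1)


def _condensed(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return squareform(D, checks=False)


def mantel(
    D1: np.ndarray,
    D2: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the condensed upper triangles; the
    null jointly permutes rows and columns of D2. One-sided p for
    positive association by default (add-one estimator); "two-sided"
    counts |null r| >= |observed r|.
    """
    D1, D2 = np.asarray(D1, float), np.asarray(D2, float)
    if D1.shape != D2.shape:
        raise ValueError("distance matrices must share shape and item order")
    v1, v2 = _condensed(D1), _condensed(D2)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in condensed distances")
    r_obs = float(pearsonr(v1, v2).statistic)
    rng = np.random.default_rng(seed)
    n = D1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = squareform(D2[np.ix_(perm, perm)], checks=False)
        r_null = float(pearsonr(v1, v2p).statistic)
        if alternative == "greater":
            count += r_null >= r_obs
        elif alternative == "two-sided":
            count += abs(r_null) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_items=n)
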