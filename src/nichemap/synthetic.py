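"""Generators for fixtures with known ground truth.

The niche-space geometry the analysis expects — discrete clusters of
unique capabilities, quasi-1D branches rising from a shared metabolic
core, phylogenetically structured traits, and ecosystem-specific
community composition — is planted here explicitly, so every pipeline
stage has a recoverable truth to be tested against. All generators are
pure functions of their spec and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityCensus, NicheSet
from .trait_matrix import TraitMatrix

__all__ = [
    "ClusterSpec",
    "BranchSpec",
    "EvolveSpec",
    "make_clustered_traits",
    "make_branching_traits",
    "make_random_tree",
    "simulate_traits_on_tree",
    "make_communities",
]


def _trait_names(n: int, prefix: str = "s") -> List[str]:
    # zero-padded so lexicographic column order equals construction order
    return [f"{prefix}{i:05d}->p{i:05d}" for i in range(n)]


@dataclass(frozen=True)
class ClusterSpec:
    """Discrete clusters sharing a metabolic core.

    Every genome carries ``n_core_traits`` shared traits; each cluster's
    members additionally carry that cluster's private block of
    ``n_unique_traits``; background genomes carry only the core. Each bit
    is then flipped independently with ``flip_prob`` (Bernoulli noise).
    """

    n_core_traits: int
    clusters: Tuple[Tuple[int, int], ...]  # (n_genomes, n_unique_traits)
    n_background_genomes: int = 0
    flip_prob: float = 0.0
    seed: int = 0
    force_unique: bool = False  # one private trait per genome (breaks ties)

    def __post_init__(self):
        object.__setattr__(self, "clusters", tuple(map(tuple, self.clusters)))
        if not 0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        if any(n < 2 for n, _ in self.clusters):
            raise ValueError("cluster sizes must be >= 2")


def make_clustered_traits(spec: ClusterSpec):
    """Binary trait matrix with planted clusters; returns (matrix, labels).

    ``labels[i]`` is the cluster index of genome i, or -1 for background.
    """
    n_genomes = sum(n for n, _ in spec.clusters) + spec.n_background_genomes
    if n_genomes < 4:
        raise ValueError("need at least 4 genomes in total")
    n_unique = sum(u for _, u in spec.clusters)
    n_priv = n_genomes if spec.force_unique else 0
    n_traits = spec.n_core_traits + n_unique + n_priv
    X = np.zeros((n_genomes, n_traits), dtype=np.uint8)
    X[:, : spec.n_core_traits] = 1
    labels = np.full(n_genomes, -1, dtype=int)
    row = 0
    col = spec.n_core_traits
    for c, (n, u) in enumerate(spec.clusters):
        X[row : row + n, col : col + u] = 1
        labels[row : row + n] = c
        row += n
        col += u
    rng = np.random.default_rng(spec.seed)
    if spec.flip_prob > 0:
        flips = rng.random(X.shape) < spec.flip_prob
        X = np.where(flips, 1 - X, X).astype(np.uint8)
    if spec.force_unique:
        X[:, spec.n_core_traits + n_unique :] = np.eye(n_genomes, dtype=np.uint8)
    ids = [f"g{i:04d}" for i in range(n_genomes)]
    return TraitMatrix(ids, _trait_names(n_traits), X), labels


@dataclass(frozen=True)
class BranchSpec:
    """Quasi-1D branches accreting traits stepwise from a common core."""

    n_branches: int
    genomes_per_branch: int
    traits_per_step: int
    n_core_traits: int
    seed: int = 0

    def __post_init__(self):
        if min(self.n_branches, self.genomes_per_branch,
               self.traits_per_step, self.n_core_traits) < 1:
            raise ValueError("all BranchSpec fields must be positive")


def make_branching_traits(spec: BranchSpec):
    """Branching trait manifold; returns (matrix, positions).

    A single shared root genome carries only the core; branch b's genome
    at step s (1-based) adds the first s*traits_per_step traits of
    branch b's pool, so within a branch the Hamming distance between
    steps s and t is |s-t|*traits_per_step. ``positions`` lists
    (branch, step) per genome, the root as (-1, 0).
    """
    per_branch = spec.genomes_per_branch * spec.traits_per_step
    n_traits = spec.n_core_traits + spec.n_branches * per_branch
    n_genomes = 1 + spec.n_branches * spec.genomes_per_branch
    X = np.zeros((n_genomes, n_traits), dtype=np.uint8)
    X[:, : spec.n_core_traits] = 1
    positions = [(-1, 0)]
    row = 1
    for b in range(spec.n_branches):
        base = spec.n_core_traits + b * per_branch
        for s in range(1, spec.genomes_per_branch + 1):
            X[row, base : base + s * spec.traits_per_step] = 1
            positions.append((b, s))
            row += 1
    ids = [f"g{i:04d}" for i in range(n_genomes)]
    return TraitMatrix(ids, _trait_names(n_traits), X), positions


def make_random_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree with exponential waiting times, unit rate.

    Binary, rooted, positive branch lengths; leaves relabeled L1..Ln in
    a deterministic traversal order. Same seed, same Newick string.
    """
    if n_leaves < 3:
        raise ValueError("n_leaves must be >= 3")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=rng,
    )
    # the simulation stops at the nth split, leaving the newest cherry
    # with zero-length tip edges; observe the process for one further
    # exponential holding time so every tip edge is positive
    hold = rng.expovariate(n_leaves)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"L{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + hold
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


@dataclass(frozen=True)
class EvolveSpec:
    """Independent two-state Markov trait evolution along a tree.

    Each trait switches 0->1 at ``gain_rate`` and 1->0 at ``loss_rate``
    per unit branch length; the root state is Bernoulli with
    ``root_presence_prob``.
    """

    n_traits: int
    gain_rate: float = 0.5
    loss_rate: float = 0.5
    root_presence_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.root_presence_prob <= 1:
            raise ValueError("root_presence_prob must lie in [0, 1]")


def _ctmc_presence_prob(parent_state, t, gain, loss):
    """P(child = 1 | parent state) from the 2-state CTMC closed form."""
    rate = gain + loss
    if rate == 0:
        return parent_state.astype(float)
    pi1 = gain / rate
    decay = np.exp(-rate * t)
    return pi1 + (parent_state - pi1) * decay


def simulate_traits_on_tree(tree: dendropy.Tree, spec: EvolveSpec) -> TraitMatrix:
    """Evolve binary traits down the tree; leaf states form the matrix."""
    rng = np.random.default_rng(spec.seed)
    root = tree.seed_node
    states = {
        root: (rng.random(spec.n_traits) < spec.root_presence_prob).astype(
            np.uint8
        )
    }
    leaf_rows = {}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            p1 = _ctmc_presence_prob(
                states[node.parent_node].astype(float), t,
                spec.gain_rate, spec.loss_rate,
            )
            states[node] = (rng.random(spec.n_traits) < p1).astype(np.uint8)
        if node.is_leaf():
            leaf_rows[node.taxon.label] = states[node]
    ids = sorted(leaf_rows)
    X = np.vstack([leaf_rows[g] for g in ids])
    return TraitMatrix(ids, _trait_names(spec.n_traits), X)


def make_communities(
    niches: Sequence[NicheSet],
    ecosystem_profiles: Mapping[str, Sequence[float]],
    n_samples_per_ecosystem: int = 20,
    match_identity: float = 98.5,
    seed: int = 0,
):
    """Assemble censuses with known niche-occupancy probabilities.

    For each sample of an ecosystem, every niche is occupied
    independently with that ecosystem's per-niche probability by adding
    the pseudo-taxon of one uniformly chosen member genome. Returns
    (censuses, match table linking each pseudo-taxon to its genome at
    ``match_identity``). A sample that ends up with no taxa raises —
    censuses must be nonempty, so raise occupancy probabilities.
    """
    rng = np.random.default_rng(seed)
    niche_members = [sorted(n.genome_ids) for n in niches]
    censuses: List[CommunityCensus] = []
    for eco in sorted(ecosystem_profiles):
        probs = np.asarray(ecosystem_profiles[eco], dtype=float)
        if probs.shape != (len(niches),):
            raise ValueError(
                f"profile for {eco!r} must have one probability per niche"
            )
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("occupancy probabilities must lie in [0, 1]")
        for s in range(n_samples_per_ecosystem):
            taxa = set()
            occupied = rng.random(len(niches)) < probs
            for j in np.where(occupied)[0]:
                members = niche_members[j]
                g = members[rng.integers(len(members))]
                taxa.add(f"tax_{g}")
            if not taxa:
                raise ValueError(
                    f"sample {eco}/{s} drew no taxa; occupancy "
                    "probabilities too low to form a census"
                )
            censuses.append(
                CommunityCensus(f"{eco}_s{s:03d}", eco, frozenset(taxa))
            )
    genomes = sorted({g for members in niche_members for g in members})
    matches = pd.DataFrame(
        {
            "taxon_id": [f"tax_{g}" for g in genomes],
            "genome_id": genomes,
            "pct_identity": match_identity,
        }
    )
    return censuses, matches
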