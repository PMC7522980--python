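"""Metabolite enrichment at diffusion-variable extrema.

For each diffusion variable, genomes are ranked by their entries and every
metabolite defines a genome set (the genomes whose networks contain it as
a node). A GSEA-style running sum walked down the ranking measures whether
a metabolite's genomes concentrate at either extreme; significance comes
from random same-size genome sets (gene-set permutation, sign-matched),
with Benjamini-Hochberg control across the metabolites tested per
variable.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .diffusion import DiffusionResult
from .trait_matrix import MetabolicNetwork

__all__ = [
    "metabolite_sets",
    "running_sum_es",
    "permutation_p",
    "bh_adjust",
    "enrich_variable",
]


def metabolite_sets(
    networks: Sequence[MetabolicNetwork],
    min_size: int = 5,
    max_size: int | None = None,
) -> Dict[str, Set[str]]:
    """Map each metabolite to the genomes whose network contains it.

    Sets with fewer than ``min_size`` or more than ``max_size`` genomes are
    dropped (default max N-5): near-empty and near-universal sets carry no
    ranking information. Empty sets never appear.
    """
    if not networks:
        raise ValueError("networks must be nonempty")
    if max_size is None:
        max_size = len(networks) - 5
    sets: Dict[str, Set[str]] = {}
    for net in networks:
        for met in net.metabolites:
            sets.setdefault(met, set()).add(net.genome_id)
    return {
        met: members
        for met, members in sets.items()
        if min_size <= len(members) <= max_size
    }


def running_sum_es(
    ranked_genomes: Sequence[str],
    stats: Sequence[float],
    member_set: Iterable[str],
    exponent: float = 1.0,
) -> float:
    """Enrichment score: signed extreme of the classic running sum.

    Walking down ``ranked_genomes`` (already ordered, with ``stats`` the
    corresponding ranking statistics), the sum rises by
    |stat|^exponent / sum_hits |stat|^exponent at members and falls by
    1/(N - |S|) at non-members. ES is the maximal deviation, positive if
    |max| >= |min| else the negative minimum; ES is in [-1, 1].
    """
    members = set(member_set)
    N = len(ranked_genomes)
    if len(stats) != N:
        raise ValueError("stats length must match ranking length")
    if not members or not members < set(ranked_genomes):
        raise ValueError("member set must be a nonempty proper subset of ranking")
    is_member = np.fromiter(
        (g in members for g in ranked_genomes), dtype=bool, count=N
    )
    n_hits = int(is_member.sum())
    if n_hits != len(members):
        raise ValueError("member set contains genomes absent from ranking")
    w = np.abs(np.asarray(stats, dtype=float)) ** exponent
    hit_total = w[is_member].sum()
    if hit_total == 0:  # all member stats zero: fall back to equal weights
        step = np.where(is_member, 1.0 / n_hits, 0.0)
    else:
        step = np.where(is_member, w / hit_total, 0.0)
    step = step - np.where(is_member, 0.0, 1.0 / (N - n_hits))
    walk = np.cumsum(step)
    hi, lo = walk.max(), walk.min()
    return float(hi if abs(hi) >= abs(lo) else lo)


def permutation_p(
    ranked_genomes: Sequence[str],
    stats: Sequence[float],
    member_set: Iterable[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exponent: float = 1.0,
) -> tuple:
    """Sign-matched permutation p-value for the enrichment score.

    The null is built from ``n_perm`` uniformly drawn genome sets of the
    same size; p = (1 + #{null ES at least as extreme, same sign}) /
    (1 + n_perm). Returns (ES, p). Deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    members = set(member_set)
    es = running_sum_es(ranked_genomes, stats, members, exponent)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    N, size = len(ranked_genomes), len(members)
    genomes = list(ranked_genomes)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(N, size=size, replace=False)
        null_es = running_sum_es(
            ranked_genomes, stats, {genomes[i] for i in idx}, exponent
        )
        if es >= 0:
            count += null_es >= es
        else:
            count += null_es <= es
    return es, (1 + count) / (1 + n_perm)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min_{j >= i} (p_(j) * m / j) over the ascending order, capped
    at 1. Raises on p outside (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_variable(
    R: DiffusionResult,
    sets: Mapping[str, Set[str]],
    variable_index: int,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Score every metabolite set against one diffusion variable's ranking.

    Genomes are ranked by the variable's entries in descending order, so
    positive ES marks enrichment toward the positive extremum and
    negative ES toward the negative one. BH adjustment is applied across
    all metabolites tested for this variable; rows with p_adj < alpha are
    flagged significant. Output is sorted by (p_adj, metabolite_id).
    """
    v = R.variable(variable_index)
    order = sorted(range(len(v)), key=lambda i: (-v[i], R.genome_ids[i]))
    ranked = [R.genome_ids[i] for i in order]
    stats = [float(v[i]) for i in order]
    rng = np.random.default_rng(seed)
    rows = []
    for met in sorted(sets):
        es, p = permutation_p(ranked, stats, sets[met], n_perm, rng, exponent)
        rows.append((met, variable_index, es, p, len(sets[met])))
    table = pd.DataFrame(
        rows, columns=["metabolite_id", "variable_index", "ES", "p", "set_size"]
    )
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(
        ["p_adj", "metabolite_id"], kind="stable"
    ).reset_index(drop=True)
    return table[
        ["metabolite_id", "variable_index", "ES", "p", "p_adj", "set_size",
         "significant"]
    ]
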