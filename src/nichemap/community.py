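"""Mapping community censuses onto extremal metabolic niches.

A niche is operationally the set of n genomes (default 10) at one
extremum (positive or negative) of one diffusion variable. A community
census occupies a niche if at least one of its taxa matches a niche
genome at >= 97% sequence identity (matching supplied as a precomputed
top-hit table). Per-ecosystem occupancy proportions across the first
2 x n_variables niches form a metabolic fingerprint, and Ward clustering
of fingerprints groups ecosystems with similar strategy repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist

from .diffusion import DiffusionResult, extremal_taxa

__all__ = [
    "NicheSet",
    "CommunityCensus",
    "filter_matches",
    "build_niches",
    "niche_occupancy",
    "occupancy_table",
    "ecosystem_fingerprint",
    "ward_clustering",
    "linkage_to_newick",
]

IDENTITY_THRESHOLD = 97.0


@dataclass(frozen=True)
class NicheSet:
    """Extremal strategy set: one (variable, sign) with its genomes."""

    variable_index: int
    sign: str  # "negative" | "positive"
    genome_ids: frozenset

    def __post_init__(self):
        if self.sign not in ("negative", "positive"):
            raise ValueError("sign must be 'negative' or 'positive'")

    @property
    def label(self) -> str:
        return f"v{self.variable_index}{'+' if self.sign == 'positive' else '-'}"


@dataclass(frozen=True)
class CommunityCensus:
    sample_id: str
    ecosystem_label: str
    taxa: frozenset

    def __post_init__(self):
        if not self.taxa:
            raise ValueError(f"census {self.sample_id!r} has no taxa")


def filter_matches(
    matches: pd.DataFrame, threshold: float = IDENTITY_THRESHOLD
) -> pd.DataFrame:
    """Keep taxon->genome matches at or above the identity threshold.

    The cut is inclusive ("97% or greater"): 97.0 is retained, 96.9 is
    not. Expects columns taxon_id, genome_id, pct_identity.
    """
    required = {"taxon_id", "genome_id", "pct_identity"}
    if not required <= set(matches.columns):
        raise ValueError(f"match table needs columns {sorted(required)}")
    pid = matches["pct_identity"].astype(float)
    if ((pid < 0) | (pid > 100)).any():
        raise ValueError("pct_identity must lie in [0, 100]")
    return matches.loc[pid >= threshold].reset_index(drop=True)


def build_niches(
    R: DiffusionResult, n_variables: int = 50, n_extremal: int = 10
) -> List[NicheSet]:
    """One NicheSet per (variable, sign) over the first n_variables.

    With the default 50 variables and 10-genome extrema this yields 100
    extremal strategies.
    """
    if R.n_variables < n_variables:
        raise ValueError(
            f"result has {R.n_variables} variables, need {n_variables}"
        )
    niches = []
    for l in range(1, n_variables + 1):
        neg, pos = extremal_taxa(R, l, n_extremal)
        niches.append(NicheSet(l, "negative", frozenset(neg)))
        niches.append(NicheSet(l, "positive", frozenset(pos)))
    return niches


def _taxon_to_genome(matches: pd.DataFrame) -> Dict[str, str]:
    # top-hit contract: one retained genome per taxon
    if matches["taxon_id"].duplicated().any():
        dupes = matches.loc[
            matches["taxon_id"].duplicated(), "taxon_id"
        ].unique()[:5]
        raise ValueError(f"multiple matches per taxon (e.g. {list(dupes)}); "
                         "retain top hits first")
    return dict(zip(matches["taxon_id"], matches["genome_id"]))


def niche_occupancy(
    census: CommunityCensus,
    matches: pd.DataFrame,
    niches: Sequence[NicheSet],
) -> np.ndarray:
    """Binary occupancy vector: 1 iff some census taxon maps into the niche.

    ``matches`` must already be identity-filtered; unmatched taxa
    contribute nothing. Abundances are ignored — one detected variant
    suffices.
    """
    t2g = _taxon_to_genome(matches)
    genomes = {t2g[t] for t in census.taxa if t in t2g}
    return np.fromiter(
        (bool(genomes & n.genome_ids) for n in niches), dtype=np.uint8,
        count=len(niches),
    )


def occupancy_table(
    censuses: Sequence[CommunityCensus],
    matches: pd.DataFrame,
    niches: Sequence[NicheSet],
) -> pd.DataFrame:
    """Per-sample occupancy matrix (samples x niche labels)."""
    rows = [niche_occupancy(c, matches, niches) for c in censuses]
    return pd.DataFrame(
        np.asarray(rows, dtype=np.uint8),
        index=pd.Index([c.sample_id for c in censuses], name="sample_id"),
        columns=[n.label for n in niches],
    )


def ecosystem_fingerprint(
    censuses: Sequence[CommunityCensus],
    matches: pd.DataFrame,
    niches: Sequence[NicheSet],
) -> pd.DataFrame:
    """Ecosystem x niche matrix of occupancy proportions.

    Entry (e, niche) is the fraction of ecosystem e's samples whose
    communities occupy the niche; rows are sorted ecosystem labels.
    """
    if not censuses:
        raise ValueError("need at least one census")
    occ = occupancy_table(censuses, matches, niches)
    eco = pd.Series(
        [c.ecosystem_label for c in censuses], index=occ.index, name="ecosystem"
    )
    fp = occ.groupby(eco, sort=True).mean()
    fp.index.name = "ecosystem"
    return fp


def ward_clustering(F: pd.DataFrame):
    """Ward minimum-variance clustering of fingerprint rows.

    Returns (linkage matrix in scipy format, leaf order as row labels).
    Euclidean distances over proportion rows; scipy's deterministic
    nearest-neighbor chain makes the output reproducible for a given
    row order.
    """
    if F.shape[0] < 2:
        raise ValueError("need at least 2 ecosystem rows to cluster")
    Z = linkage(pdist(F.to_numpy(), metric="euclidean"), method="ward")
    order = [F.index[i] for i in leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick dendrogram string."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    # root has no parent branch: strip its trailing length
    return render(root, root.dist).rsplit(":", 1)[0] + ";"


def censuses_from_long(df: pd.DataFrame) -> List[CommunityCensus]:
    """Build censuses from long-format (sample_id, ecosystem_label, taxon_id)."""
    required = {"sample_id", "ecosystem_label", "taxon_id"}
    if not required <= set(df.columns):
        raise ValueError(f"census table needs columns {sorted(required)}")
    eco = df.groupby("sample_id")["ecosystem_label"].nunique()
    if (eco > 1).any():
        bad = eco[eco > 1].index.tolist()[:5]
        raise ValueError(f"samples with conflicting ecosystem labels: {bad}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(
            CommunityCensus(
                sample_id=str(sid),
                ecosystem_label=str(grp["ecosystem_label"].iloc[0]),
                taxa=frozenset(grp["taxon_id"].astype(str)),
            )
        )
    return out
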