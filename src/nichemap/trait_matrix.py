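"""Binary genome x trait matrices built from directed metabolic networks.

A genome's metabolism is summarized as a directed graph whose nodes are
metabolite compounds and whose edges link substrates to products. Each
unique directed edge observed anywhere in a genome collection defines one
binary "trait"; a genome scores 1 for a trait iff its network contains that
edge. The resulting presence/absence matrix is the coordinate input for
the diffusion map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicNetwork",
    "TraitMatrix",
    "read_network_edgelist",
    "read_networks_dir",
    "read_networks_table",
    "build_trait_matrix",
    "drop_constant_traits",
    "deduplicate_genomes",
]

EDGE_SEP = "->"


@dataclass(frozen=True)
class MetabolicNetwork:
    """A directed substrate->product graph for one genome.

    Parameters
    ----------
    genome_id : str
        Non-empty identifier for the genome.
    edges : frozenset of (str, str)
        Directed (substrate, product) pairs.
    metabolites : frozenset of str
        Metabolite node identifiers; always a superset of edge endpoints.
    """

    genome_id: str
    edges: frozenset = field(default_factory=frozenset)
    metabolites: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        endpoints = {m for e in self.edges for m in e}
        if not endpoints <= self.metabolites:
            object.__setattr__(
                self, "metabolites", frozenset(self.metabolites) | endpoints
            )


@dataclass
class TraitMatrix:
    """Genome x trait binary presence/absence matrix.

    ``trait_names`` are ``"substrate->product"`` labels in lexicographic
    order; ``values`` is an (n_genomes, n_traits) uint8 array.
    """

    genome_ids: list
    trait_names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.genome_ids), len(self.trait_names)):
            raise ValueError("values shape does not match ids/names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("trait matrix entries must be binary")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome_ids")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("duplicate trait names")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genome_ids, name="genome_id"),
            columns=self.trait_names,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


def read_network_edgelist(path, genome_id: str) -> MetabolicNetwork:
    """Read one genome's network from a two-column TSV edge list.

    Each non-comment line holds ``substrate<TAB>product``. Duplicate lines
    collapse to a single edge. Lines starting with ``#`` are ignored.
    """
    edges = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}: {line!r}"
                )
            edges.add((fields[0].strip(), fields[1].strip()))
    if not edges:
        warnings.warn(f"{path}: empty edge list for genome {genome_id!r}")
    return MetabolicNetwork(genome_id=genome_id, edges=frozenset(edges))


def read_networks_dir(directory) -> list:
    """Read every ``*.tsv`` edge list in a directory; filename stem = genome_id."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv edge lists under {directory}")
    return [read_network_edgelist(p, p.stem) for p in paths]


def read_networks_table(path) -> list:
    """Read a single 3-column TSV (genome_id, substrate, product)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["genome_id", "substrate", "product"], dtype=str,
    )
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed row with missing fields")
    networks = []
    for gid, grp in df.groupby("genome_id", sort=True):
        edges = frozenset(zip(grp["substrate"], grp["product"]))
        networks.append(MetabolicNetwork(genome_id=str(gid), edges=edges))
    return networks


def trait_label(substrate: str, product: str) -> str:
    return f"{substrate}{EDGE_SEP}{product}"


def build_trait_matrix(networks: Sequence[MetabolicNetwork]) -> TraitMatrix:
    """Assemble the binary genome x trait matrix from a genome collection.

    Trait columns are the lexicographically sorted union of all directed
    edges; genome rows preserve input order. Direction matters: A->B and
    B->A are distinct traits.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    ids = [n.genome_id for n in networks]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome_id(s): {dupes}")
    all_edges = sorted({e for n in networks for e in n.edges})
    col = {e: j for j, e in enumerate(all_edges)}
    values = np.zeros((len(networks), len(all_edges)), dtype=np.uint8)
    for i, net in enumerate(networks):
        for e in net.edges:
            values[i, col[e]] = 1
    names = [trait_label(s, p) for s, p in all_edges]
    return TraitMatrix(ids, names, values)


def drop_constant_traits(T: TraitMatrix) -> TraitMatrix:
    """Remove columns identical across all genomes.

    Pairwise Euclidean row distances are unchanged: a constant column
    contributes zero to every squared difference.
    """
    keep = ~(T.values == T.values[0]).all(axis=0) if len(T.genome_ids) else []
    keep = np.asarray(keep, dtype=bool)
    if not keep.any():
        raise ValueError("no variable traits remain")
    if keep.all():
        return T
    names = [n for n, k in zip(T.trait_names, keep) if k]
    return TraitMatrix(list(T.genome_ids), names, T.values[:, keep])


def deduplicate_genomes(T: TraitMatrix):
    """Collapse genomes with identical trait rows to one representative.

    The kNN similarity graph rejects duplicate rows (zero distance means
    infinite inverse-distance weight); merge duplicates first and
    re-expand results afterwards. Returns (matrix keeping the first
    member of each duplicate group, mapping representative -> list of
    merged genome_ids including itself).
    """
    _, rep_idx, inv = np.unique(
        T.values, axis=0, return_index=True, return_inverse=True
    )
    keep = np.zeros(len(T.genome_ids), dtype=bool)
    first_of_group = {}
    for i in range(len(T.genome_ids)):  # input order: first occurrence wins
        g = inv[i]
        if g not in first_of_group:
            first_of_group[g] = i
            keep[i] = True
    groups = {}
    for i in range(len(T.genome_ids)):
        rep = T.genome_ids[first_of_group[inv[i]]]
        groups.setdefault(rep, []).append(T.genome_ids[i])
    kept_ids = [g for g, k in zip(T.genome_ids, keep) if k]
    return TraitMatrix(kept_ids, list(T.trait_names), T.values[keep]), groups
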