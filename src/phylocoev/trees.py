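"""Phylogeny container, tree I/O, pruning, covariances and distances.

Trees are parsed and written with dendropy (Newick and NEXUS); internally
they are stored as a compact array-based structure (preorder node indexing,
parent pointers, per-edge lengths) on which the comparative-method
computations in the rest of the package operate.

The module also provides the linguistic-vs-geographic distance correlation:
Pearson's r over the n(n-1)/2 unordered tip pairs of two distance matrices,
with a parametric test on n(n-1)/2 - 2 degrees of freedom and an optional
Mantel permutation test (pairwise distances are not independent, so the
parametric p-value should be read as descriptive).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

__all__ = [
    "Phylogeny",
    "TreeSample",
    "DistanceMatrix",
    "parse_trees",
    "prune_to_taxa",
    "phylo_vcv",
    "lambda_transform",
    "patristic_distances",
    "great_circle_distances",
    "distance_correlation",
    "EARTH_RADIUS_KM",
]


class Phylogeny:
    """Rooted tree with branch lengths, stored as parallel arrays.

    Nodes are indexed in preorder with the root at index 0, so every node's
    parent index is smaller than its own.  ``edge_length[i]`` is the length
    of the edge above node ``i`` (0 for the root).  ``labels[i]`` is the tip
    label for leaves and ``None`` for internal nodes.
    """

    def __init__(self, parent: np.ndarray, edge_length: np.ndarray, labels: list):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if n == 0:
            raise ValueError("empty tree")
        if self.edge_length.size != n or len(self.labels) != n:
            raise ValueError("array length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != 0:
            raise ValueError("exactly one root required, at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be in preorder (parent index < child)")
        if np.any(self.edge_length[1:] < 0):
            raise ValueError("negative branch length")
        tips = self.tip_indices
        tip_labels = [self.labels[i] for i in tips]
        if any(l is None for l in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        # children lists, computed once
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self._children[self.parent[i]].append(i)

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tip_indices(self) -> np.ndarray:
        is_tip = np.ones(self.parent.size, dtype=bool)
        is_tip[self.parent[self.parent >= 0]] = False
        return np.flatnonzero(is_tip)

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    def children(self, i: int) -> list[int]:
        return self._children[i]

    def postorder(self) -> np.ndarray:
        """Node indices, children before parents (reverse preorder works)."""
        return np.arange(self.n_nodes - 1, -1, -1)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.edge_length[i]
        return d

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        elen = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else None
        return cls(parent, elen, labels)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = [None] * self.n_nodes
        dnodes[0] = tree.seed_node
        for i in range(1, self.n_nodes):
            nd = dendropy.Node()
            nd.edge.length = float(self.edge_length[i])
            dnodes[self.parent[i]].add_child(nd)
            dnodes[i] = nd
        for i in self.tip_indices:
            dnodes[i].taxon = tns.require_taxon(label=self.labels[i])
        return tree

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_trees(text, "newick").trees[0]

    def newick(self) -> str:
        """Newick string with branch lengths to 12 significant digits."""
        out = self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
            unquoted_underscores=True,
        )
        return out.strip()


@dataclass
class TreeSample:
    """Ordered collection of trees sharing a single taxon set."""

    trees: list[Phylogeny]
    source_format: str = "newick"

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree sample")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {k} has a different tip label set")

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance (or covariance) matrix."""

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (the n(n-1)/2 unordered pairs)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------


def parse_trees(text: str, format: str = "newick") -> TreeSample:
    """Parse one or more trees from a Newick or NEXUS string."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(data=text, schema=format)
    except Exception as e:  # dendropy raises schema-specific errors w/ position
        raise ValueError(f"malformed {format} input: {e}") from e
    if len(tl) == 0:
        raise ValueError("no trees found in input")
    return TreeSample([Phylogeny.from_dendropy(t) for t in tl], source_format=format)


def write_trees(sample: TreeSample, path, format: str = "newick") -> None:
    """Write a tree sample to a file in Newick or NEXUS format."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in sample.trees:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    kwargs = {"real_value_format_specifier": ".12g", "unquoted_underscores": True}
    if format == "newick":
        kwargs["suppress_rooting"] = True
    tl.write(path=str(path), schema=format, **kwargs)


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict a tree to a subset of tips.

    Unary internal nodes created by the pruning are collapsed with their
    branch lengths summed, so patristic distances among kept tips are
    preserved exactly.
    """
    keep = set(keep)
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    missing = sorted(keep - set(tree.tip_labels))
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    dtree = tree.to_dendropy()
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    dtree.retain_taxa(taxa)
    return Phylogeny.from_dendropy(dtree)


def _mrca_depths(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """(tip depths, matrix of MRCA depths) in tip_indices order."""
    depths = tree.node_depths()
    tips = tree.tip_indices
    n = tips.size
    pos = {int(t): k for k, t in enumerate(tips)}
    below: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    mrca = np.zeros((n, n))
    for i in tree.postorder():
        kids = tree.children(i)
        if not kids:
            below[i] = [pos[int(i)]]
            mrca[pos[int(i)], pos[int(i)]] = depths[i]
            continue
        acc: list[int] = []
        for c in kids:
            for a in acc:
                for b in below[c]:
                    mrca[a, b] = mrca[b, a] = depths[i]
            acc.extend(below[c])
            below[c] = []
        below[i] = acc
    return depths[tips], mrca


def phylo_vcv(tree: Phylogeny) -> DistanceMatrix:
    """Brownian-motion covariance implied by the tree.

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal holds the tip depths.  The result is a Gram matrix and hence
    positive semidefinite.
    """
    tip_depths, mrca = _mrca_depths(tree)
    return DistanceMatrix(tree.tip_labels, mrca, units="tree-time")


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of a correlation matrix by lambda in [0, 1]."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Sum of branch lengths along the tip-to-tip path, for all tip pairs."""
    if tree.n_tips < 2:
        raise ValueError("need >= 2 tips")
    tip_depths, mrca = _mrca_depths(tree)
    d = tip_depths[:, None] + tip_depths[None, :] - 2.0 * mrca
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tree.tip_labels, d, units="tree-time")


def great_circle_distances(coords, labels=None) -> DistanceMatrix:
    """Haversine great-circle distances (km) between (lat, lon) points."""
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("coords must be a sequence of (lat, lon) pairs")
    lat, lon = np.radians(arr[:, 0]), np.radians(arr[:, 1])
    if np.any(np.abs(arr[:, 0]) > 90) or np.any(np.abs(arr[:, 1]) > 180):
        raise ValueError("coordinates out of range (lat +-90, lon +-180)")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    labels = labels or [str(i) for i in range(arr.shape[0])]
    return DistanceMatrix(list(labels), d, units="km")


def distance_correlation(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "parametric",
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Pearson correlation between two distance matrices over tip pairs.

    The parametric test treats the n(n-1)/2 pairs as independent
    observations (df = n(n-1)/2 - 2, 95% CI via Fisher's z); ``method=
    "mantel"`` adds a permutation p-value that respects the matrix
    structure by permuting taxa jointly.
    """
    if D1.labels != D2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(D1.labels)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    x, y = D1.condensed(), D2.condensed()
    r = float(np.corrcoef(x, y)[0, 1])
    npairs = n * (n - 1) // 2
    df = npairs - 2
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r_)
    se = 1.0 / np.sqrt(npairs - 3)
    ci = np.tanh([z - 1.959963984540054 * se, z + 1.959963984540054 * se])
    with np.errstate(divide="ignore"):
        tstat = r_ * np.sqrt(df / (1 - r_**2))
    p = float(2 * stats.t.sf(abs(tstat), df))
    out = {"r": r, "ci_low": float(ci[0]), "ci_high": float(ci[1]), "df": df, "p": p}
    if method == "mantel":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n, k=1)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            yp = D2.values[np.ix_(perm, perm)][iu]
            if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r):
                count += 1
        out["p_mantel"] = (count + 1) / (n_permutations + 1)
    elif method != "parametric":
        raise ValueError("method must be 'parametric' or 'mantel'")
    return out
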