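"""Diversity and dissimilarity statistics on an OTU table + phylogeny.

Implements, from first principles, the 16S summary statistics of the
analysis: observed OTUs and Faith's phylogenetic diversity ("PD whole
tree"), taxonomy collapse to relative abundances, unweighted UniFrac,
classical PCoA, PERMANOVA, and rarefaction.  Newick parsing and the tree
container come from scikit-bio; every metric here is computed directly from
branch lengths and counts rather than delegated.

Faith's PD is the total branch length of the minimal subtree spanning a
sample's observed leaves and the root.  Unweighted UniFrac between two
samples is the branch length leading exclusively to leaves observed in only
one of them, divided by the branch length leading to leaves observed in
either.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "PhyloTree",
    "DistanceMatrix",
    "rarefy",
    "observed_otus",
    "faith_pd",
    "parse_lineage",
    "collapse_taxonomy",
    "unweighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "permanova",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("counts shape does not match sample/OTU ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())


class PhyloTree:
    """Rooted phylogeny over OTU ids with non-negative branch lengths.

    Wraps a scikit-bio TreeNode and precomputes, per non-root edge, its
    length and the set of descendant leaves, as arrays over a fixed leaf
    order -- this makes PD and UniFrac single matrix products.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        leaves = list(tree.tips())
        self.leaf_names = [t.name for t in leaves]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf names in tree")
        index = {n: i for i, n in enumerate(self.leaf_names)}
        edges: list[tuple[float, np.ndarray]] = []
        for node in tree.postorder(include_self=False):
            bl = 0.0 if node.length is None else float(node.length)
            if bl < 0:
                raise ValueError("negative branch length")
            mask = np.zeros(len(leaves), dtype=bool)
            for tip in node.tips(include_self=True):
                mask[index[tip.name]] = True
            edges.append((bl, mask))
        self.edge_lengths = np.array([e[0] for e in edges])
        # (n_edges, n_leaves) indicator: leaf j descends from edge i
        self.edge_leaves = (
            np.vstack([e[1] for e in edges])
            if edges
            else np.zeros((0, len(leaves)), dtype=bool)
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read([newick]))

    def leaf_indices(self, otu_ids: Sequence[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.leaf_names)}
        missing = [o for o in otu_ids if o not in index]
        if missing:
            raise KeyError(f"OTUs absent from tree: {missing[:10]}")
        return np.array([index[o] for o in otu_ids], dtype=int)

    def edge_presence(self, presence: np.ndarray, otu_ids: Sequence[str]) -> np.ndarray:
        """Map sample x OTU presence to sample x edge presence."""
        idx = self.leaf_indices(otu_ids)
        sub = self.edge_leaves[:, idx]  # edges x otus
        return np.asarray(presence, bool) @ sub.T > 0


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < -1e-12):
            raise ValueError("negative distances")


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals
    if np.all(totals < depth):
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    keep_ids: list[str] = []
    rows: list[np.ndarray] = []
    for sid, row, tot in zip(table.sample_ids, table.counts, totals):
        if tot < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, tot, depth)
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    return OtuTable(keep_ids, list(table.otu_ids), np.vstack(rows))


def observed_otus(sample_counts: Sequence[float]) -> int:
    """Richness: number of OTUs with count > 0."""
    counts = np.asarray(sample_counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return int(np.count_nonzero(counts))


def faith_pd(
    sample_counts: Sequence[float], tree: PhyloTree, otu_ids: Sequence[str]
) -> float:
    """Faith's PD: branch length of the subtree spanning observed leaves + root."""
    counts = np.asarray(sample_counts)
    if counts.shape != (len(otu_ids),):
        raise ValueError("counts and otu_ids length mismatch")
    pres = (counts > 0)[None, :]
    on = tree.edge_presence(pres, otu_ids)[0]
    return float(tree.edge_lengths[on].sum())


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a 'k__...;p__...;...;g__...' string into rank -> name."""
    out = dict.fromkeys(RANKS, "")
    for part in lineage.split(";"):
        part = part.strip()
        for rank, pref in zip(RANKS, _PREFIXES):
            if part.lower().startswith(pref):
                out[rank] = part[len(pref):].strip()
    return out


def taxon_label(lineage: str, rank: str) -> str:
    """Taxon name at ``rank``; falls back to '<nearest named ancestor>;Other'."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    parsed = parse_lineage(lineage)
    if parsed[rank]:
        return parsed[rank]
    for anc in reversed(RANKS[: RANKS.index(rank)]):
        if parsed[anc]:
            return f"{parsed[anc]};Other"
    return "Other"


def collapse_taxonomy(
    table: OtuTable, taxonomy: Mapping[str, str], rank: str
) -> pd.DataFrame:
    """Relative abundances at a rank (rows = samples, sum to 1).

    OTUs without a name at the rank aggregate under '<parent>;Other',
    mirroring genus-level labels like 'Lachnospiraceae;Other'.
    """
    labels = [taxon_label(taxonomy.get(o, ""), rank) for o in table.otu_ids]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=labels)
    collapsed = df.T.groupby(level=0).sum().T
    totals = collapsed.sum(axis=1)
    if np.any(totals.to_numpy() == 0):
        raise ValueError("cannot form relative abundances for an empty sample")
    return collapsed.div(totals, axis=0)


def unweighted_unifrac(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    tree: PhyloTree,
    otu_ids: Sequence[str],
) -> float:
    """Presence-based UniFrac distance between two samples, in [0, 1]."""
    a = np.asarray(sample_a)
    b = np.asarray(sample_b)
    if not a.any() or not b.any():
        raise ValueError("unweighted UniFrac requires both samples non-empty")
    on = tree.edge_presence(np.vstack([a > 0, b > 0]), otu_ids)
    ea, eb = on[0], on[1]
    union = float(tree.edge_lengths[ea | eb].sum())
    if union == 0.0:
        return 0.0
    unique = float(tree.edge_lengths[ea ^ eb].sum())
    return unique / union


def unifrac_matrix(table: OtuTable, tree: PhyloTree) -> DistanceMatrix:
    """All-pairs unweighted UniFrac for every sample in the table."""
    if np.any(table.sample_totals == 0):
        raise ValueError("unweighted UniFrac requires non-empty samples")
    on = tree.edge_presence(table.counts > 0, table.otu_ids)  # samples x edges
    L = tree.edge_lengths
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        xor = on[i][None, :] ^ on[i + 1 :]
        orr = on[i][None, :] | on[i + 1 :]
        uni = xor @ L
        tot = orr @ L
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, uni / np.maximum(tot, 1e-300), 0.0)
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass(frozen=True)
class PCoAResult:
    coordinates: np.ndarray  # samples x kept axes, eigenvalue-descending
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  Negative eigenvalues are
    reported but their axes dropped.  Sign convention: within each axis the
    largest-|loading| coordinate is made positive.
    """
    D = d.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0)) if n else 0.0
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = evals[keep].sum()
    prop = evals[keep] / pos_sum if pos_sum > 0 else evals[keep]
    return PCoAResult(coords, evals, prop)


def _permanova_stat(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    k = groups.size
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: DistanceMatrix, groups: Sequence, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from total vs within-group sums of squared distances; p-value
    is (1 + #{permuted F >= observed}) / (1 + n_perm) under free label
    permutation.  Deterministic given ``seed``.
    """
    labels = np.asarray(groups)
    if labels.size != len(d.sample_ids):
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 samples")
    d2 = d.data**2
    f_obs = _permanova_stat(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_stat(d2, perm, uniq) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)
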