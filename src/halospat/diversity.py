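"""Alpha and beta diversity from first principles.

Count tables are pandas DataFrames with samples as rows and amplicon
sequence variants (ASVs) as columns; phylogenies are rooted scikit-bio
``TreeNode`` objects whose tip names match the table's columns.
Dissimilarities are returned as ``skbio.DistanceMatrix``.

Conventions follow the QIIME-era pipeline this package re-implements:
Shannon entropy in bits (log base 2), weighted UniFrac unnormalized by
default, rarefaction without replacement at the minimum sample depth.
"""

from __future__ import annotations

import io
import itertools
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "read_counts",
    "read_tree",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "OrdinationResult",
]

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("shannon", "simpson", "pielou", "faith_pd")


def read_counts(path) -> pd.DataFrame:
    """Read a samples × ASVs count table from TSV (samples as rows)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    _validate_table(table)
    return table


def read_tree(source) -> TreeNode:
    """Read a rooted Newick tree; tip labels are ASV ids.

    Accepts a path or a Newick string.  Unlabeled internal nodes and
    zero-length branches are permitted.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source))
    return TreeNode.read(str(source))


def _validate_table(table: pd.DataFrame, allow_zero_samples: bool = False) -> None:
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("duplicate sample or ASV ids in count table")
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if not allow_zero_samples and (table.sum(axis=1) == 0).any():
        empty = table.index[table.sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with zero total counts: {empty}")


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (ids recorded in
    ``result.attrs['dropped']`` and logged).  Deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    _validate_table(table)
    totals = table.sum(axis=1)
    keep = totals.index[totals >= depth]
    if keep.empty:
        raise ValueError(f"rarefaction depth {depth} exceeds every sample total")
    dropped = totals.index.difference(keep).tolist()
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, sid in enumerate(keep):
        counts = table.loc[sid].to_numpy(dtype=np.int64)
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    result = pd.DataFrame(out, index=keep, columns=table.columns)
    result.attrs["dropped"] = dropped
    return result


def _tip_presence_and_lengths(table: pd.DataFrame, tree: TreeNode):
    """Per-branch descendant count matrix and branch lengths.

    Returns (counts_per_branch, lengths): for every non-root node of the
    tree (postorder), the total table counts descending through that branch
    per sample, and the branch length (None treated as 0).
    """
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.columns) - tips)
    if missing:
        raise ValueError(f"ASVs missing from the tree: {missing}")
    col_index = {name: j for j, name in enumerate(table.columns)}
    x = table.to_numpy(dtype=float)
    n_samples = x.shape[0]

    node_counts: dict[int, np.ndarray] = {}
    branch_counts, lengths = [], []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col_index.get(node.name)
            vec = x[:, j] if j is not None else np.zeros(n_samples)
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec = vec + node_counts[id(child)]
        node_counts[id(node)] = vec
        if node.parent is not None:  # root carries no branch
            branch_counts.append(vec)
            lengths.append(node.length or 0.0)
    return np.array(branch_counts), np.array(lengths)


def alpha_diversity(
    table: pd.DataFrame, metric: str, tree: TreeNode | None = None
) -> pd.Series:
    """Per-sample alpha diversity.

    shannon: −Σ p log₂ p (bits); simpson: 1 − Σ p²;
    pielou: shannon / log₂(richness), NaN for single-ASV samples;
    faith_pd: total branch length of the minimal subtree spanning the root
    and all tips present (requires ``tree``).
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")
    _validate_table(table)
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    p = x / totals

    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a phylogeny")
        branch_counts, lengths = _tip_presence_and_lengths(table, tree)
        present = branch_counts > 0  # (n_branches, n_samples)
        values = lengths @ present
    elif metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        values = -terms.sum(axis=1)
    elif metric == "simpson":
        values = 1.0 - (p**2).sum(axis=1)
    else:  # pielou
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        shannon = -terms.sum(axis=1)
        richness = (x > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(richness > 1, shannon / np.log2(richness), np.nan)
    return pd.Series(values, index=table.index, name=metric)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC(a,b) = Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ).

    Computed on the table as given (counts or relative abundances; the two
    agree when sample totals are equal).
    """
    _validate_table(table)
    if len(table) < 2:
        raise ValueError("need at least two samples")
    x = table.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    return DistanceMatrix(num / den, ids=list(table.index))


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac: Σ_branches length · |P_a − P_b| where P_x is the
    fraction of sample x's reads descending through the branch.

    The normalized variant divides by Σ length · (P_a + P_b).  Unnormalized
    is the default, matching the pipeline convention this package mirrors.
    """
    _validate_table(table)
    if len(table) < 2:
        raise ValueError("need at least two samples")
    branch_counts, lengths = _tip_presence_and_lengths(table, tree)
    totals = table.to_numpy(dtype=float).sum(axis=1)
    p = branch_counts / totals  # (n_branches, n_samples)

    n = len(table)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        diff = np.abs(p[:, i] - p[:, j])
        val = float(lengths @ diff)
        if normalized:
            denom = float(lengths @ (p[:, i] + p[:, j]))
            val = val / denom if denom > 0 else 0.0
        d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=list(table.index))


class OrdinationResult:
    """Principal-coordinates (classical scaling) result.

    Attributes
    ----------
    coordinates : pandas.DataFrame
        Sample coordinates on the axes with positive eigenvalues
        (columns PC1, PC2, ...).
    proportion_explained : ndarray
        Fraction of positive-eigenvalue variance per retained axis,
        non-increasing.
    eigenvalues : ndarray
        All eigenvalues in decreasing order, negatives included (reported,
        never clipped).
    """

    def __init__(self, coordinates, proportion_explained, eigenvalues):
        self.coordinates = coordinates
        self.proportion_explained = np.asarray(proportion_explained)
        self.eigenvalues = np.asarray(eigenvalues)

    def __repr__(self) -> str:  # pragma: no cover
        k = self.coordinates.shape[1]
        return f"<OrdinationResult: {len(self.coordinates)} samples, {k} axes>"


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers −½D², eigen-decomposes, and retains axes with positive
    eigenvalues; negative eigenvalues (non-Euclidean input) are reported in
    ``eigenvalues``.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # enforces symmetry / zero diagonal
    d2 = dm.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * n * np.finfo(float).eps
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PC{k + 1}" for k in range(pos.sum())]
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        proportion_explained=prop,
        eigenvalues=eigvals,
    )
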