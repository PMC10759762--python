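"""Trait-based phenetics: standardization, average Euclidean distance, UPGMA.

The trait matrix is a taxa × variables table (e.g. leaf dimensions,
numerically encoded flower colours, and the karyotype statistics A1, A2 and
TCL). Variables are z-scored column-wise, pairwise dissimilarity is the
average (root-mean-square) Euclidean distance, and the dendrogram is UPGMA
(average linkage), which is ultrametric by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import InputError

logger = logging.getLogger(__name__)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score with sample standard deviation (n−1).

    Constant columns carry no information and are mapped to zero with a
    warning. Idempotent on already-standardized data.
    """
    if matrix.shape[0] < 2:
        raise InputError("standardization needs at least two taxa")
    if matrix.isna().any().any():
        raise InputError("trait matrix contains missing cells")
    out = matrix.astype(float).copy()
    sd = out.std(ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("constant trait columns set to zero: %s", list(sd[constant].index))
    for col in out.columns:
        if constant[col]:
            out[col] = 0.0
        else:
            out[col] = (out[col] - out[col].mean()) / sd[col]
    return out


def average_euclidean(matrix: pd.DataFrame, kind: str = "avg-euclidean") -> pd.DataFrame:
    """Pairwise distance matrix over taxa (rows).

    ``avg-euclidean`` (default) is the root-mean-square difference over the
    p variables, d(i,j) = sqrt(Σ_k (x_ik − x_jk)² / p); ``euclidean`` is the
    plain unscaled form.
    """
    x = matrix.to_numpy(dtype=float)
    d = pdist(x, metric="euclidean")
    if kind == "avg-euclidean":
        d = d / np.sqrt(x.shape[1])
    elif kind != "euclidean":
        raise InputError(f"unknown distance kind: {kind!r}")
    return pd.DataFrame(squareform(d), index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """UPGMA tree: scipy linkage matrix plus leaf labels.

    Node heights are half the merge distance, so leaf-to-leaf path height
    equals half the cophenetic distance (the conventional ultrametric
    drawing).
    """

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format, distances not halved

    @property
    def merge_heights(self) -> list[float]:
        return [row[2] / 2.0 for row in self.linkage_matrix]

    def cophenetic(self) -> pd.DataFrame:
        d = cophenet(self.linkage_matrix)
        return pd.DataFrame(squareform(d), index=self.labels, columns=self.labels)

    def newick(self, decimals: int = 6) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.labels[i] for i in range(n)}
        for k, (a, b, dist, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            h = dist / 2.0
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + k] = (
                f"({nodes[a]}:{la:.{decimals}f},{nodes[b]}:{lb:.{decimals}f})"
            )
            heights[n + k] = h
        return nodes[n + len(self.linkage_matrix) - 1] + ";"

    def merges(self) -> list[dict]:
        """Merge order as JSON-friendly records (children ids, height)."""
        out = []
        for k, (a, b, dist, size) in enumerate(self.linkage_matrix):
            out.append(
                {
                    "node": len(self.labels) + k,
                    "children": [int(a), int(b)],
                    "height": dist / 2.0,
                    "size": int(size),
                }
            )
        return out


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """UPGMA (unweighted average-linkage) dendrogram from a distance matrix."""
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise InputError("distance matrix must be square with n >= 2")
    if np.isnan(d).any():
        raise InputError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise InputError("distance matrix is not symmetric")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=[str(t) for t in distance.index], linkage_matrix=z)


def two_clade_topology(tree: Dendrogram) -> tuple[set[str], set[str]] | None:
    """For a 4-taxon tree, the two leaf bipartitions below the root, if balanced.

    Returns None when the root join is leaf-vs-triple (caterpillar shape).
    """
    n = len(tree.labels)
    members: dict[int, set[str]] = {i: {tree.labels[i]} for i in range(n)}
    for k, (a, b, *_rest) in enumerate(tree.linkage_matrix):
        members[n + k] = members[int(a)] | members[int(b)]
    root = tree.linkage_matrix[-1]
    left, right = members[int(root[0])], members[int(root[1])]
    if len(left) < 2 or len(right) < 2:
        return None
    return left, right


def read_trait_table(path) -> pd.DataFrame:
    """TSV trait table: first column taxon labels, header = variable names."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError("trait table needs a taxon column and >= 1 variable")
    return df.set_index(df.columns[0])
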