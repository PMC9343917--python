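"""Distance matrices, neighbor-joining trees and PCA ordination.

Distances operate on two representations of the panel: the 1/0 allelic
matrix (Jaccard) and the raw call matrix (simple matching). Positions
missing in either row are excluded pairwise in both cases.

The neighbor-joining implementation follows the Saitou–Nei agglomeration
with the standard Q-criterion. Its decisive correctness property is that it
reproduces any additive distance matrix exactly: leaf-to-leaf path lengths
through the reconstructed tree equal the input distances. Negative branch
lengths are clamped to zero with the deficit transferred to the sister edge;
tie-breaks are lexicographic over the smallest leaf label in each clade so
that results are deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import DegenerateInputError, UndefinedValueError, ValidationError
from .model import Call, GenotypeMatrix, encode_binary

# -- pairwise distances ----------------------------------------------------


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Jaccard similarity between two binary allele-presence rows.

    With M11 the count of shared 1s and M10/M01 the mismatches over mutually
    non-missing positions, similarity = M11 / (M11 + M10 + M01). Positions
    that are NaN in either row are excluded pairwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rows differ in length")
    both = ~np.isnan(a) & ~np.isnan(b)
    m11 = int(((a == 1) & (b == 1) & both).sum())
    m_mismatch = int(((a != b) & both).sum())
    denom = m11 + m_mismatch
    if denom == 0:
        raise UndefinedValueError("Jaccard undefined: no informative positions")
    return 1.0 - m11 / denom


def jaccard_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances over the panel's 1/0 allelic matrix."""
    binary = encode_binary(gm)
    n = gm.n_cultivars
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(binary[i], binary[j])
    return DistanceMatrix(d, ids=gm.cultivar_ids)


def simple_matching_distance(
    gm: GenotypeMatrix,
    cultivar_a: str,
    cultivar_b: str,
    panel: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of mutually called panel loci at which two cultivars differ."""
    cols = (
        [gm.marker_index(m) for m in panel] if panel is not None else slice(None)
    )
    a = gm.calls[gm.cultivar_index(cultivar_a), cols]
    b = gm.calls[gm.cultivar_index(cultivar_b), cols]
    both = (a != Call.MISSING) & (b != Call.MISSING)
    n_both = int(both.sum())
    if n_both == 0:
        raise UndefinedValueError("no mutually called loci")
    return float(((a != b) & both).sum() / n_both)


def simple_matching_distance_matrix(
    gm: GenotypeMatrix, panel: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    ids = gm.cultivar_ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = simple_matching_distance(gm, ids[i], ids[j], panel)
    return DistanceMatrix(d, ids=ids)


# -- neighbor joining ------------------------------------------------------


def _min_leaf(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree (trifurcate root).

    On an additive input the tip-to-tip path lengths equal the input
    distances exactly (up to floating-point error). Ties in the Q-criterion
    break on the lexicographically smallest pair of clade labels, where a
    clade is labelled by its smallest leaf name.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    labels: list[str] = list(dm.ids)

    def join(i: int, j: int, li: float, lj: float) -> None:
        # clamp negative estimates, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj = nodes[i], nodes[j]
        ni.length = max(li, 0.0)
        nj.length = max(lj, 0.0)
        parent = TreeNode(children=[ni, nj])
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        del nodes[j]
        del labels[j]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_key = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # distances from the new node to every remaining node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        join(i, j, li, lj)
        dnew = np.delete(dnew, j)
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
    # closed-form three-point resolution
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
    return TreeNode(children=list(nodes))


# -- newick ----------------------------------------------------------------

_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _newick_label(name: Optional[str]) -> str:
    if not name:
        return ""
    if _UNQUOTED_OK.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize a tree as Newick with fixed-precision branch lengths.

    Labels containing whitespace or Newick metacharacters are quoted per the
    format convention; parse-then-serialize is the identity on topology and
    lengths at the chosen precision.
    """

    def render(node: TreeNode) -> str:
        label = _newick_label(node.name)
        if not node.is_tip():
            label = "(" + ",".join(render(c) for c in node.children) + ")" + label
        if node.length is not None:
            label += f":{node.length:.{precision}f}"
        return label

    return render(tree) + ";"


def tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity oracle helper)."""
    return tree.tip_tip_distances()


# -- PCA -------------------------------------------------------------------


@dataclass
class PCAResult:
    """Sample coordinates and per-component variance proportions."""

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(gm: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the genotype matrix.

    Genotypes are coded 0/1/2 (allele2 dosage), missing calls are imputed
    with the marker mean and columns are centered; the decomposition is the
    SVD of the centered matrix. Variance proportions are relative to the
    total variance over all components. Component signs are fixed by making
    the largest-magnitude marker loading positive.
    """
    if gm.n_cultivars < 2:
        raise ValidationError("PCA needs >= 2 cultivars")
    X = gm.calls.astype(float)
    X[X == Call.MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    if not (np.abs(X) > 1e-12).any():
        raise DegenerateInputError("all markers are constant; PCA undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((s**2).sum())
    k = min(n_components, len(s))
    coords = U[:, :k] * s[:k]
    ratios = (s[:k] ** 2) / total_var
    for c in range(k):
        load = Vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    return PCAResult(
        coordinates=pd.DataFrame(
            coords, index=gm.cultivar_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=ratios,
    )
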