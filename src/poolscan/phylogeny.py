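"""Neighbor-joining tree from the pairwise mean-F_ST distance matrix.

Standard Saitou–Nei agglomeration: repeatedly join the pair (i, j)
minimizing Q(i, j) = (n-2) d(i, j) - r_i - r_j (r = row sums), with ties
broken deterministically by smallest index pair; branch lengths by the
usual formulas.  The final three clusters are resolved into an unrooted
star, so leaf-to-leaf path lengths reproduce additive input distances
exactly.  Negative branch lengths are retained (and logged), matching the
behavior of the classical Phylip implementation.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

from .sync_io import StructuralError

logger = logging.getLogger("poolscan")


def _validate_matrix(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 3:
        raise StructuralError("distance matrix must be square with n >= 3")
    if list(d.index) != list(d.columns):
        raise StructuralError("distance matrix row/column labels differ")
    if not np.allclose(m, m.T, atol=1e-12):
        raise StructuralError("distance matrix not symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise StructuralError("distance matrix diagonal not zero")
    return m


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Build an unrooted NJ tree from a labeled symmetric distance matrix.

    Returns a :class:`skbio.TreeNode` whose (trifurcating) root is the last
    internal node; leaves are named by the matrix labels.
    """
    m = _validate_matrix(d)
    labels = [str(x) for x in d.index]
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    dist = m.copy()
    neg = False

    while len(nodes) > 3:
        n = len(nodes)
        r = dist.sum(axis=1)
        q = (n - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) with i < j on ties: scan upper triangle row-major
        iu = np.triu_indices(n, k=1)
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = dist[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dist[i, j] - li
        neg |= (li < 0) or (lj < 0)
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        nd = np.zeros((n - 1, n - 1))
        nd[:-1, :-1] = dist[np.ix_(keep, keep)]
        nd[-1, :-1] = nd[:-1, -1] = new_d[keep]
        dist = nd
        nodes = [nodes[x] for x in keep] + [parent]

    # resolve the last three clusters into an unrooted star
    root = TreeNode()
    (a, b, c) = (0, 1, 2)
    lengths = (
        (dist[a, b] + dist[a, c] - dist[b, c]) / 2.0,
        (dist[a, b] + dist[b, c] - dist[a, c]) / 2.0,
        (dist[a, c] + dist[b, c] - dist[a, b]) / 2.0,
    )
    for node, length in zip(nodes, lengths):
        neg |= length < 0
        node.length = float(length)
        root.append(node)
    if neg:
        logger.warning("neighbor_joining: tree contains negative branch lengths (retained)")
    return root


_UNQUOTED = re.compile(r"^[^\s()\[\]':;,]+$")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if _UNQUOTED.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _to_newick(node: TreeNode) -> str:
    if node.is_tip():
        s = _newick_label(node.name)
    else:
        s = "(" + ",".join(_to_newick(c) for c in node.children) + ")" + _newick_label(node.name)
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def tree_to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths; names needing it are single-quoted."""
    return _to_newick(tree) + ";\n"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def read_newick(path: str | Path) -> TreeNode:
    return skbio.read(str(path), format="newick", into=TreeNode,
                      convert_underscores=False)


def leaf_distances(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix (for additivity checks)."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_distance_matrix(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path, sep="\t", float_format="%.8g")
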