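"""Neighbor-joining tumor phylogenies from deleterious-mutation profiles.

Pairwise sample distance is the Hamming count over the binary mutation
matrix (variants present in exactly one of the two samples). An optional
germline pseudo-sample with an all-zero profile provides an outgroup root.
The NJ join order minimizes the classic Q criterion with a deterministic
lexicographic tie-break; negative branch lengths are clamped to zero.
"""
from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .variants import MutationMatrix

GERMLINE_LABEL = "germline"


def mutation_distance_matrix(
    m: MutationMatrix, include_germline_root: bool = True
) -> DistanceMatrix:
    """Hamming distances between samples over deleterious variants."""
    if len(m.sample_ids) < 2:
        raise ValueError("need at least two samples")
    x = m.presence.astype(np.int32)
    labels = list(m.sample_ids)
    if include_germline_root:
        if GERMLINE_LABEL in labels:
            raise ValueError(f"sample id {GERMLINE_LABEL!r} is reserved")
        x = np.vstack([x, np.zeros(x.shape[1], dtype=np.int32)])
        labels.append(GERMLINE_LABEL)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j
    (r = row sums over active nodes); ties are broken by the lexicographically
    smallest pair of representative leaf labels. Terminates in an unrooted
    tree whose root is the final trifurcation (bifurcation for 4 taxa resolves
    naturally). Exact on additive distances.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    keys: list[str] = list(labels)  # smallest leaf label per active node
    d = dm.data.astype(float).copy()

    def _clamp(length: float) -> float:
        if length < 0:
            if length < -1e-9:
                warnings.warn(f"negative NJ branch length {length:.3g} clamped to 0")
            return 0.0
        return length

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp((dab + dac - dbc) / 2)
    b.length = _clamp((dab + dbc - dac) / 2)
    c.length = _clamp((dac + dbc - dab) / 2)
    return TreeNode(children=[a, b, c])


def root_at_germline(tree: TreeNode, label: str = GERMLINE_LABEL) -> TreeNode:
    """Reroot an unrooted NJ tree on the edge leading to the germline leaf."""
    return tree.root_by_outgroup([label])


def build_tree(
    m: MutationMatrix, include_germline_root: bool = True
) -> tuple[TreeNode, DistanceMatrix]:
    """Distance matrix + NJ tree (rooted at germline when requested)."""
    dm = mutation_distance_matrix(m, include_germline_root)
    tree = neighbor_joining(dm)
    if include_germline_root:
        tree = root_at_germline(tree)
    return tree, dm


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def to_newick(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
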