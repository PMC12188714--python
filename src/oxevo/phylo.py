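"""Distance-based tree building and relative divergence-time estimation.

``nj_tree`` is a from-scratch Saitou–Nei neighbor-joining implementation
(Studier–Keppler Q-criterion); on additive distance matrices it recovers
the generating topology and path lengths exactly.

``reltime`` implements a relative-rate framework in its branch-length
form: at every node the two (or more) descendant lineages are constrained
to have elapsed the same relative time, with per-lineage rates absorbing
the branch-length differences; lineage depths are averaged with weights
equal to descendant tip counts. Node times are then propagated root-to-tip
and normalized so the root is at relative time 1 and tips at 0. No fossil
calibration is involved — only relative divergence order and depth.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode


def _as_distance_matrix(matrix, labels=None) -> DistanceMatrix:
    if isinstance(matrix, DistanceMatrix):
        dm = matrix
    else:
        dm = DistanceMatrix(np.asarray(matrix, dtype=float), ids=labels)
    if (dm.data < 0).any():
        raise ValueError("distance matrix entries must be non-negative")
    return dm


def nj_tree(matrix, labels=None) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Returns an unrooted tree represented with a trifurcating root. Ties in
    the Q-criterion are broken by the smallest (i, j) index pair, making
    the output deterministic.
    """
    dm = _as_distance_matrix(matrix, labels)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    D = dm.data.copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])

        # reuse slot i for the merged node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = new
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, length in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def root_by_outgroup(tree: TreeNode, outgroup_labels) -> TreeNode:
    """Root a tree on the branch separating the outgroup, at its midpoint.

    The outgroup must be exactly one side of a single edge of the unrooted
    topology (i.e. a clade); otherwise the call fails.
    """
    outgroup = set(outgroup_labels)
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    t = tree.copy()
    all_tips = {tip.name for tip in t.tips()}
    missing = outgroup - all_tips
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if outgroup == all_tips:
        raise ValueError("outgroup cannot contain every taxon")

    target = None
    for node in t.postorder(include_self=False):
        tipset = {tip.name for tip in node.tips(include_self=True)}
        if tipset == outgroup or (all_tips - tipset) == outgroup:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not monophyletic in the unrooted tree")

    length = target.length if target.length is not None else 0.0
    rooted = t.root_at(target, above=length / 2 if length > 0 else True, reset=True)
    return rooted


def _collapse_zero_internal(tree: TreeNode, tol: float = 0.0) -> TreeNode:
    """Collapse zero-length internal branches (tips are left alone)."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder(include_self=False)):
            if node.children and node.length is not None and node.length <= tol:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True
    return t


def reltime(tree: TreeNode, weighted: bool = True) -> TreeNode:
    """Relative node times and per-lineage relative rates.

    The input must be rooted (bifurcating root) with non-negative branch
    lengths; zero-length internal branches are collapsed first, so
    polytomies arising from that collapse are handled. Returns an annotated
    copy whose nodes carry ``rel_time`` (root 1, tips 0) and, on every
    non-root node, ``rel_rate`` = branch length / elapsed relative time.

    With ``weighted`` (default) the depth of an ancestral lineage is the
    mean of its descendant lineage depths weighted by tip counts; the
    unweighted alternative averages the child lineages equally.
    """
    if tree.parent is not None:
        raise ValueError("input must be the root of a tree")
    if len(tree.children) != 2:
        raise ValueError("tree must be rooted (bifurcating root); root it first")
    n_tips = sum(1 for _ in tree.tips())
    if n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    for node in tree.postorder(include_self=False):
        if node.length is None or node.length < 0:
            raise ValueError("all branch lengths must be present and non-negative")

    t = _collapse_zero_internal(tree)

    # bottom-up: equalized lineage depth h (substitution units) per node
    for node in t.postorder(include_self=True):
        if not node.children:
            node._rt_tips = 1
            node._rt_h = 0.0
        else:
            node._rt_tips = sum(c._rt_tips for c in node.children)
            ws = [c._rt_tips if weighted else 1 for c in node.children]
            depths = [c.length + c._rt_h for c in node.children]
            node._rt_h = float(np.average(depths, weights=ws))
    root_h = t._rt_h
    if root_h <= 0:
        raise ValueError("tree has zero total depth; relative times undefined")

    # top-down: relative times (root = 1) and per-branch relative rates
    t.rel_time = 1.0
    t.rel_rate = None
    for node in t.preorder(include_self=False):
        parent_time = node.parent.rel_time
        denom = node.length + node._rt_h
        factor = node._rt_h / denom if denom > 0 else 0.0
        node.rel_time = parent_time * factor
        dt = parent_time - node.rel_time
        node.rel_rate = node.length / dt if dt > 0 else np.nan
    for node in t.postorder(include_self=True):
        del node._rt_tips
        del node._rt_h
    return t


def reltime_table(annotated: TreeNode):
    """Node times/rates of a ``reltime`` result as a DataFrame."""
    import pandas as pd

    rows = []
    for i, node in enumerate(annotated.preorder(include_self=True)):
        rows.append(
            {
                "node": node.name if node.name else f"internal_{i}",
                "is_tip": not node.children,
                "rel_time": node.rel_time,
                "rel_rate": node.rel_rate,
                "branch_length": node.length,
            }
        )
    return pd.DataFrame(rows)
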