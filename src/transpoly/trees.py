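"""Distance matrices, neighbor-joining, Fitch parsimony and Newick I/O.

Trees are ``dendropy.Tree`` objects throughout; leaf taxon labels equal
the alignment record ids, so downstream modules (codon selection test,
trans-species test) are agnostic about whether a tree was built here by
neighbor joining or imported from an external Newick file.

Neighbor joining is the classic Saitou-Nei agglomeration with the
Studier-Keppler Q-criterion.  Ties in Q are broken by the
lexicographically smallest label pair so repeated runs are identical.
Negative branch lengths (possible on non-additive input) are clamped to
zero with a warning.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .seqio import Alignment

__all__ = [
    "pdistance_matrix",
    "nj_tree",
    "fitch_score",
    "bootstrap_support",
    "read_newick",
    "write_newick",
]



def pdistance_matrix(aln: Alignment, mode: str = "pairwise-deletion"):
    """Pairwise p-distance over gap-free compared columns.

    Returns ``(labels, D)`` with a symmetric zero-diagonal matrix.
    ``mode='complete-deletion'`` first drops every column containing a
    gap or N in any sequence; ``'pairwise-deletion'`` (default) drops
    columns per pair.  A pair with no comparable column raises.
    """
    if mode not in ("pairwise-deletion", "complete-deletion"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = aln.to_array()
    labels = aln.ids
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record ids; tree building needs unique labels")
    ok = ~(np.isin(arr, ("-", "N")))
    if mode == "complete-deletion":
        keep = ok.all(axis=0)
        arr = arr[:, keep]
        ok = ok[:, keep]
    n = arr.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = int(comp.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable (gap-free) columns between "
                    f"{labels[i]!r} and {labels[j]!r}"
                )
            diff = int((arr[i, comp] != arr[j, comp]).sum())
            D[i, j] = D[j, i] = diff / m
    return labels, D


def _new_tree(namespace_labels):
    tns = dendropy.TaxonNamespace(namespace_labels)
    return dendropy.Tree(taxon_namespace=tns), tns


def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric zero-diagonal matrix.

    Recovers additive trees exactly.  The result is unrooted (the seed
    node is a trifurcation for >=3 taxa).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need >=3 taxa for neighbor joining")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    tree, tns = _new_tree(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    # sort key per working node: smallest leaf label underneath
    keys = list(labels)
    D = dist.copy()
    active = list(range(n))

    clamped = False
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None  # (Q, key_pair, ai, aj)
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                kp = tuple(sorted((keys[idx[a]], keys[idx[b]])))
                cand = (q, kp, a, b)
                if best is None or (q < best[0] - 1e-12) or (
                    abs(q - best[0]) <= 1e-12 and kp < best[1]
                ):
                    best = cand
        _, _, a, b = best
        i, j = idx[a], idx[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to the remaining ones
        newrow = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = idx[c]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the final three on a central node
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    if min(li, lj, lk) < 0:
        clamped = True
    center = tree.seed_node
    for nd, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        center.add_child(nd)
        nd.edge.length = max(ln, 0.0)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    tree.is_rooted = False
    return tree


def fitch_score(tree: dendropy.Tree, leaf_states: dict[str, str]):
    """Small-parsimony (Fitch) score plus one optimal assignment.

    ``leaf_states`` maps leaf taxon labels to character states.  Ties in
    the up-pass are broken by the smallest state under sorted order, so
    the returned assignment is deterministic.  Returns
    ``(score, assignment)`` with assignment keyed by leaf label for
    leaves and by node id for internal nodes.
    """
    score = 0
    downsets: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else None
            if lab not in leaf_states:
                raise ValueError(f"leaf {lab!r} has no state label")
            downsets[id(nd)] = frozenset([leaf_states[lab]])
        else:
            sets = [downsets[id(ch)] for ch in nd.child_nodes()]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    score += 1
            downsets[id(nd)] = acc

    assignment: dict = {}
    states: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        ds = downsets[id(nd)]
        parent = nd.parent_node
        if parent is None:
            st = min(ds)
        else:
            pst = states[id(parent)]
            st = pst if pst in ds else min(ds)
        states[id(nd)] = st
        if nd.is_leaf():
            assignment[nd.taxon.label] = st
        else:
            assignment[id(nd)] = st
    return score, assignment


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical frozensets of leaf labels."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bips = set()
    for nd in tree.postorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return bips


def bootstrap_support(
    aln: Alignment, n_reps: int = 100, seed: int = 0, mode: str = "pairwise-deletion"
) -> dendropy.Tree:
    """NJ tree with bootstrap support (column resampling).

    Support fractions for the point-estimate tree's internal edges are
    stored as internal node labels (and ``node.support``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, D = pdistance_matrix(aln, mode=mode)
    point = nj_tree(D, labels)
    target = {b: 0 for b in _bipartitions(point)}

    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    L = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = _resampled_pdistance(arr, labels, cols)
        rt = nj_tree(rep, labels)
        for b in _bipartitions(rt):
            if b in target:
                target[b] += 1

    all_leaves = frozenset(labels)
    for nd in point.postorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        frac = target[key] / n_reps
        nd.label = f"{frac:.2f}"
        nd.support = frac
    return point


def _resampled_pdistance(arr: np.ndarray, labels, cols) -> np.ndarray:
    sub = arr[:, cols]
    ok = ~np.isin(sub, ("-", "N"))
    n = sub.shape[0]
    D = np.zeros((n, n))
    fallback = 0.0
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = int(comp.sum())
            if m == 0:
                pairs.append((i, j))
                continue
            d = int((sub[i, comp] != sub[j, comp]).sum()) / m
            D[i, j] = D[j, i] = d
            fallback = max(fallback, d)
    # a pair with no comparable resampled column gets the replicate's
    # maximum distance (rare; keeps the replicate usable)
    for i, j in pairs:
        D[i, j] = D[j, i] = fallback
    return D


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")
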