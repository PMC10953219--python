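"""Neighbour-joining tree construction and bootstrap supports.

Saitou-Nei agglomeration with the Q-criterion. Determinism contract:
ties in Q are broken by the label-sorted (i, j) pair, and negative
branch-length estimates are clamped to zero (the raw value is logged).
On an additive distance matrix NJ recovers the generating topology and
branch lengths exactly, which is the primary oracle used in the tests.
"""

from __future__ import annotations

import numpy as np

from .align import DistanceMatrix, distance_matrix
from .core_io import SeqRecord, log
from .tree import Tree, TreeNode


def _clamp(length: float, context: str) -> float:
    if length < 0:
        log("INFO", "nj", f"negative branch length {length:.6g} clamped to 0 ({context})")
        return 0.0
    return length


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Build an NJ tree; the unrooted result is returned rooted at the
    final join (a trifurcation for n >= 3)."""
    M = np.asarray(D.matrix, dtype=float)
    if np.isnan(M).any():
        raise ValueError("distance matrix contains NaN")
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        d = M[0, 1]
        return Tree(TreeNode(children=[
            TreeNode(name=D.labels[0], branch_length=d / 2),
            TreeNode(name=D.labels[1], branch_length=d / 2)]))

    nodes = [TreeNode(name=lab) for lab in D.labels]
    keys = list(D.labels)  # tie-break key: smallest leaf label under node
    dist = M.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key, i, j)
        _q, _key, i, j = best
        dij = dist[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ctx = f"{keys[i]}+{keys[j]}"
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = _clamp(li, ctx)
        child_j.branch_length = _clamp(lj, ctx)
        new_node = TreeNode(children=[child_i, child_j])
        new_dists = [(dist[i, k] + dist[j, k] - dij) / 2
                     for k in range(m) if k not in (i, j)]
        keep = [k for k in range(m) if k not in (i, j)]
        nodes = [nodes[k] for k in keep] + [new_node]
        new_keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        old = dist[np.ix_(keep, keep)]
        dist = np.zeros((m - 1, m - 1))
        dist[:-1, :-1] = old
        dist[-1, :-1] = dist[:-1, -1] = new_dists
        keys = new_keys

    # final three-way join: closed form
    a, b, c = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    a.branch_length = _clamp((dab + dac - dbc) / 2, "final")
    b.branch_length = _clamp((dab + dbc - dac) / 2, "final")
    c.branch_length = _clamp((dac + dbc - dab) / 2, "final")
    return Tree(TreeNode(children=[a, b, c]))


def _resample_columns(msa: list[SeqRecord], idx: np.ndarray) -> list[SeqRecord]:
    return [SeqRecord(r.id, r.description, "".join(r.sequence[i] for i in idx))
            for r in msa]


def bootstrap_support(msa: list[SeqRecord], n_reps: int = 1000,
                      seed: int = 0, model: str = "p") -> Tree:
    """NJ tree on the full MSA with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate tree's bipartitions are tallied and the support of an
    internal edge of the full-data tree is ``100 * count / n_reps``,
    rounded to an integer. Replicates in which some pair of rows has no
    comparable columns are discarded (logged); more than 50% discards is
    an error.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(distance_matrix(msa, model))
    rng = np.random.default_rng(seed)
    L = len(msa[0].sequence)
    counts: dict[frozenset, int] = {}
    discarded = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        try:
            rep_tree = neighbor_joining(distance_matrix(_resample_columns(msa, idx), model))
        except ValueError as exc:
            discarded += 1
            log("WARNING", "bootstrap", f"replicate discarded: {exc}")
            continue
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    if discarded > n_reps / 2:
        raise ValueError(f"{discarded}/{n_reps} bootstrap replicates discarded")

    all_leaves = frozenset(full.leaf_names())
    anchor = min(all_leaves)

    def below(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        acc = frozenset()
        for ch in node.children:
            acc |= below(ch)
        return acc

    def annotate(node):
        for child in node.children:
            side = below(child)
            if 2 <= len(side) <= len(all_leaves) - 2 and not child.is_leaf:
                canon = all_leaves - side if anchor in side else side
                child.support = int(round(100 * counts.get(canon, 0) / n_reps))
            annotate(child)

    annotate(full.root)
    return full
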