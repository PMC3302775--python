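"""Neighbour-Joining trees and Maximum Length SubTree core sampling.

The NJ implementation is the standard Saitou-Nei agglomeration with the
Studier-Keppler Q-criterion.  It is written here rather than borrowed
because the redundancy-removal sampler needs (a) per-leaf terminal branch
lengths after a documented negative-length clamping rule and (b) fully
deterministic tie-breaking, neither of which library trees guarantee.

The MLST sampler iteratively removes, from the pair of closest
accessions in the dissimilarity matrix, the one with the shorter
terminal edge in the current tree, rebuilding the tree after every
removal, until the requested core size is reached.  Because removals are
nested, the recorded removal order yields the core subset of every
intermediate size for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DissimilarityMatrix

__all__ = ["Tree", "nj_tree", "mlst_subset", "MLSTResult"]


@dataclass
class Tree:
    """Unrooted tree as an undirected adjacency with branch lengths."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # keys stored with sorted endpoints
    leaves: list[str]

    def _adj(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
        for (a, b), w in self.edges.items():
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def terminal_edge_length(self, leaf: str) -> float:
        """Length of the single edge attached to a leaf."""
        for (a, b), w in self.edges.items():
            if a == leaf or b == leaf:
                return w
        raise KeyError(f"leaf {leaf!r} not in tree")

    def to_newick(self) -> str:
        """Newick string rooted at an arbitrary internal node."""
        adj = self._adj()
        leafset = set(self.leaves)
        root = next((n for n in self.nodes if n not in leafset), self.nodes[0])

        def rec(node: str, parent: str | None) -> str:
            children = [(c, w) for c, w in adj[node] if c != parent]
            if not children:
                return node
            inner = ",".join(f"{rec(c, node)}:{w:.10g}" for c, w in children)
            return f"({inner})" if node not in leafset else f"({inner}){node}"

        return rec(root, None) + ";"


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def nj_tree(d: DissimilarityMatrix) -> Tree:
    """Neighbour-Joining tree (Saitou & Nei, Studier-Keppler criterion).

    Negative branch lengths produced at a join are clamped to zero with
    the deficit transferred to the sister branch, so the path length
    between the two joined nodes is preserved.  Ties in the Q-criterion
    are broken by lexicographic order of the (sorted) node-label pair,
    making the topology deterministic.
    """
    n = d.n
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(d.values).any():
        raise ValueError("NJ needs a complete dissimilarity matrix")
    labels = list(d.accession_ids)
    D = d.values.astype(float).copy()
    edges: dict[tuple[str, str], float] = {}
    nodes = list(labels)
    next_internal = 0

    active = list(range(n))  # indices into D rows/cols
    names = {i: labels[i] for i in active}

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break: lexicographically smallest sorted label pair
        tie = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((names[idx[a]], names[idx[b]]))), int(a), int(b))
            for a, b in tie
            if a < b
        )
        _, ai, bi = best
        i, j = idx[ai], idx[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li  # transfer deficit to sister
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_name = f"_nj{next_internal}"
        next_internal += 1
        nodes.append(new_name)
        edges[_edge_key(names[i], new_name)] = li
        edges[_edge_key(names[j], new_name)] = lj
        # distances from the new node
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        names[i] = new_name
        active.remove(j)

    # final three-node star, three-point formulas
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = f"_nj{next_internal}"
    nodes.append(center)
    for node_i, length in ((a, la), (b, lb), (c, lc)):
        edges[_edge_key(names[node_i], center)] = max(length, 0.0)
    return Tree(nodes=nodes, edges=edges, leaves=labels)


@dataclass
class MLSTResult:
    """Removal order and retained core of an MLST run."""

    removed: list[str]  # in removal order
    retained: list[str]  # input order preserved

    def retained_at(self, size: int, all_ids: list[str]) -> list[str]:
        """Core subset of any size reachable along the removal path."""
        n = len(all_ids)
        if not len(self.retained) <= size <= n:
            raise ValueError(f"size {size} not on the removal path")
        dropped = set(self.removed[: n - size])
        return [a for a in all_ids if a not in dropped]


def mlst_subset(d: DissimilarityMatrix, target_n: int) -> MLSTResult:
    """Maximum Length SubTree sampling down to ``target_n`` accessions.

    Loop until the requested size: rebuild the NJ tree on the current
    subset, locate the pair with the smallest dissimilarity (closest
    genotypes, judged on the input matrix), and remove whichever member
    has the smaller terminal branch in the tree.  Distance ties break by
    lexicographic pair order; terminal-edge ties remove the
    lexicographically smaller id.  Deterministic by construction.
    """
    n = d.n
    if not 2 <= target_n <= n:
        raise ValueError(f"target_n={target_n} must be in [2, {n}]")
    current = list(d.accession_ids)
    removed: list[str] = []
    while len(current) > target_n:
        sub = d.subset(current)
        if len(current) >= 3:
            tree = nj_tree(sub)
        else:
            tree = None
        vals = sub.values.copy()
        iu = np.triu_indices(len(current), k=1)
        pair_vals = vals[iu]
        dmin = pair_vals.min()
        candidates = [
            tuple(sorted((current[i], current[j])))
            for i, j in zip(*iu)
            if np.isclose(vals[i, j], dmin, rtol=0, atol=1e-15)
        ]
        x, y = min(candidates)
        if tree is not None:
            ex, ey = tree.terminal_edge_length(x), tree.terminal_edge_length(y)
        else:
            ex = ey = 0.0
        if ex < ey:
            drop = x
        elif ey < ex:
            drop = y
        else:
            drop = min(x, y)
        removed.append(drop)
        current.remove(drop)
    return MLSTResult(removed=removed, retained=current)
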