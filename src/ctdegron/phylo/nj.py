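"""Saitou–Nei neighbor joining, exact on additive distance matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError
from .tree import PhyloTree, TreeNode

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal, labelled rows."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidArgumentError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise InvalidArgumentError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InvalidArgumentError("diagonal must be zero")
        if np.any(self.values < 0):
            raise InvalidArgumentError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        """PHYLIP-style square matrix as TSV."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic tie-breaking.

    Pair selection minimizes the Q criterion; ties are broken by the
    lexicographically smallest (min leaf label) pair. Negative branch
    lengths are clamped to zero and the total deficit logged on the
    returned tree as ``clamped_deficit``.
    """
    n = dm.n
    if n < 3:
        raise InvalidArgumentError(f"neighbor joining needs >= 3 taxa, got {n}")

    d = dm.values.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    # representative (min) leaf label per active cluster, for tie-breaking
    reps = list(dm.labels)
    active = list(range(n))
    clamped = 0.0

    def tie_key(i: int, j: int) -> tuple[str, str]:
        a, b = reps[i], reps[j]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + 1e-12:
                    key = tie_key(active[ai], active[aj])
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += -li
            li = 0.0
        if lj < 0:
            clamped += -lj
            lj = 0.0

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        # distances from the new node to every other active cluster
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # join the last three clusters at a trifurcating basal node
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += -length
            length = 0.0
        nodes[idx].length = length
        root.add_child(nodes[idx])

    tree = PhyloTree(root)
    tree.clamped_deficit = clamped
    if clamped > 0:
        log.info("NJ clamped negative branch lengths; total deficit %.6g", clamped)
    return tree


def additive_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree (for oracles and tests)."""
    leaves = tree.leaves()
    labels = [l.name for l in leaves]
    # depth of every node from root, then d(u,v) = depth(u)+depth(v)-2*depth(lca)
    import itertools

    def path_to_root(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    n = len(leaves)
    values = np.zeros((n, n))
    for (i, u), (j, v) in itertools.combinations(enumerate(leaves), 2):
        pu = path_to_root(u)
        pv = set(path_to_root(v))
        lca = next(x for x in pu if x in pv)
        dist = 0.0
        x = u
        while x is not lca:
            dist += x.length
            x = x.parent
        x = v
        while x is not lca:
            dist += x.length
            x = x.parent
        values[i, j] = values[j, i] = dist
    return DistanceMatrix(labels=labels, values=values)
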