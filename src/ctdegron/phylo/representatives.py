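"""Clade-based representative selection: cut long edges, return medoids."""

from __future__ import annotations

from ..errors import InvalidArgumentError
from .nj import DistanceMatrix
from .tree import PhyloTree, TreeNode


def _leaf_groups(tree: PhyloTree, cut: set[int]) -> list[set[str]]:
    """Leaf label sets of the components left after removing ``cut`` edges."""
    # adjacency over nodes, skipping cut edges (edge owned by child node)
    groups = []
    seen: set[int] = set()
    all_nodes = list(tree.postorder())
    for start in all_nodes:
        if id(start) in seen:
            continue
        comp_leaves: set[str] = set()
        stack = [start]
        seen.add(id(start))
        while stack:
            node = stack.pop()
            if node.is_leaf:
                comp_leaves.add(node.name)
            for child in node.children:
                if id(child) not in cut and id(child) not in seen:
                    seen.add(id(child))
                    stack.append(child)
            parent = node.parent
            if parent is not None and id(node) not in cut and id(parent) not in seen:
                seen.add(id(parent))
                stack.append(parent)
        groups.append(comp_leaves)
    return [g for g in groups if g]


def select_representatives(tree: PhyloTree, dm: DistanceMatrix,
                           n_groups: int = 8) -> list[str]:
    """Cut the longest edges into ``n_groups`` leaf groups; return medoids.

    Internal edges are preferred over leaf edges; within each class edges
    are cut longest-first (ties by the smallest leaf label below the
    edge). Each group contributes the leaf minimizing its mean distance
    to the rest of the group, ties broken by label. Results are ordered
    by each group's smallest leaf label.
    """
    n_leaves = tree.n_leaves
    if not (1 <= n_groups <= n_leaves):
        raise InvalidArgumentError(
            f"n_groups must be in [1, {n_leaves}], got {n_groups}"
        )

    def edge_key(node: TreeNode):
        internal = 0 if not node.is_leaf else 1
        below = min(tree.leafset_below(node))
        return (internal, -node.length, below)

    candidates = sorted(tree.edges(), key=edge_key)
    cut: set[int] = set()
    groups = _leaf_groups(tree, cut)
    for node in candidates:
        if len(groups) >= n_groups:
            break
        trial = cut | {id(node)}
        trial_groups = _leaf_groups(tree, trial)
        # skip cuts that strand a leafless component (no gain in groups)
        if len(trial_groups) > len(groups):
            cut = trial
            groups = trial_groups
    if len(groups) != n_groups:
        raise InvalidArgumentError(
            f"could not partition tree into {n_groups} leaf groups"
        )

    idx = {lab: i for i, lab in enumerate(dm.labels)}
    reps = []
    for group in sorted(groups, key=min):
        members = sorted(group)
        if len(members) == 1:
            reps.append(members[0])
            continue
        best = None
        for cand in members:
            mean_d = sum(dm.values[idx[cand], idx[other]]
                         for other in members if other != cand) / (len(members) - 1)
            if best is None or (mean_d, cand) < best:
                best = (mean_d, cand)
        reps.append(best[1])
    return reps
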