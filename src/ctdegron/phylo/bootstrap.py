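"""Felsenstein column bootstrap for NJ trees built from an alignment."""

from __future__ import annotations

from collections import Counter

import numpy as np

from ..errors import InvalidArgumentError
from .msa import MultipleAlignment, alignment_distance_matrix
from .nj import nj_tree
from .tree import PhyloTree


def tree_from_alignment(aln: MultipleAlignment) -> PhyloTree:
    """NJ tree from aligned p-distances of the full alignment."""
    return nj_tree(alignment_distance_matrix(aln))


def bootstrap_support(aln: MultipleAlignment, n_replicates: int = 100,
                      seed: int | None = None) -> PhyloTree:
    """NJ tree with internal-edge supports from column resampling.

    Columns are resampled with replacement ``n_replicates`` times; per
    replicate, aligned p-distances are rebuilt and NJ rerun. Support on
    each internal edge of the full-data tree is the percentage of
    replicates whose tree contains the same leaf bipartition.
    """
    if aln.n_rows < 4:
        raise InvalidArgumentError(
            f"bootstrap needs >= 4 rows (no internal edges below that), got {aln.n_rows}"
        )
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")

    main = tree_from_alignment(aln)
    rng = np.random.default_rng(seed)
    ncols = aln.n_columns
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(n_replicates):
        idx = rng.integers(0, ncols, size=ncols)
        rep_dm = alignment_distance_matrix(aln, columns=idx)
        rep_tree = nj_tree(rep_dm)
        counts.update(rep_tree.bipartitions().keys())

    for split, node in main.bipartitions().items():
        node.support = int(round(100.0 * counts[split] / n_replicates))
    return main
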