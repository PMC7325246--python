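"""Progressive multiple alignment: NJ guide tree + profile-profile merges.

The aligner makes no optimality claim beyond pairwise; its contract is the
ungap invariant (every row, with gaps removed, equals its input sequence)
plus sensible small-case behaviour under sum-of-pairs column scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError
from ..seqio import SequenceFamily
from .nj import DistanceMatrix, nj_tree
from .pairwise import ScoringScheme, _affine_dp, global_align, p_distance


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over a sequence family."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.row_ids) != len(self.rows):
            raise InvalidArgumentError("row_ids and rows length mismatch")
        if not self.rows:
            raise InvalidArgumentError("alignment must have at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise InvalidArgumentError("all rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def take_columns(self, idx) -> "MultipleAlignment":
        rows = ["".join(r[j] for j in idx) for r in self.rows]
        return MultipleAlignment(row_ids=list(self.row_ids), rows=rows)

    def write_fasta(self, path, wrap: int = 60) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n")
                for k in range(0, len(row), wrap):
                    fh.write(row[k:k + wrap] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "MultipleAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(row_ids=ids, rows=rows)


def aligned_p_distance(row_a: str, row_b: str) -> float:
    """Mismatch fraction over columns where neither row has a gap."""
    num = den = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        den += 1
        if x != y:
            num += 1
    return num / den if den else 1.0


def alignment_distance_matrix(aln: MultipleAlignment,
                              columns=None) -> DistanceMatrix:
    """Pairwise aligned p-distances, optionally on a column subset."""
    rows = aln.rows if columns is None else [
        "".join(r[j] for j in columns) for r in aln.rows
    ]
    n = len(rows)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = aligned_p_distance(rows[i], rows[j])
    return DistanceMatrix(labels=list(aln.row_ids), values=values)


def _profile_align(rows_a: list[str], rows_b: list[str],
                   scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Align two gapped profiles; returns both with new gap columns inserted."""
    n, m = len(rows_a[0]), len(rows_b[0])
    # reversed column order, matching the traceback convention of _affine_dp
    cols_a = ["".join(r[i] for r in rows_a) for i in reversed(range(n))]
    cols_b = ["".join(r[j] for r in rows_b) for j in reversed(range(m))]
    ge = scheme.gap_extend

    def col_score(i, j):
        ca, cb = cols_a[i - 1], cols_b[j - 1]
        total = 0.0
        for x in ca:
            for y in cb:
                if x == "-" and y == "-":
                    continue
                total += -ge if ("-" in (x, y)) else scheme.score(x, y)
        return total / (len(ca) * len(cb))

    ia, ib, _ = _affine_dp(n, m, col_score, scheme.gap_open, scheme.gap_extend)
    out_a = ["".join(cols_a[i - 1][k] if i else "-" for i in ia)[::-1]
             for k in range(len(rows_a))]
    out_b = ["".join(cols_b[j - 1][k] if j else "-" for j in ib)[::-1]
             for k in range(len(rows_b))]
    return out_a, out_b


def progressive_msa(family: SequenceFamily,
                    scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Multiple alignment via NJ guide tree and profile merges.

    Rows come back in family order. A single-record family yields a
    trivial one-row alignment; two records reduce to pairwise alignment.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    recs = list(family)
    if len(recs) == 1:
        return MultipleAlignment(row_ids=[recs[0].id], rows=[recs[0].sequence])
    if len(recs) == 2:
        aln = global_align(recs[0].sequence, recs[1].sequence, scheme)
        return MultipleAlignment(row_ids=[recs[0].id, recs[1].id],
                                 rows=[aln.aligned_a, aln.aligned_b])

    n = len(recs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = p_distance(
                recs[i].sequence, recs[j].sequence, scheme)
    guide = nj_tree(DistanceMatrix(labels=[r.id for r in recs], values=values))

    by_id = {r.id: r for r in recs}
    # post-order merge: each internal guide node combines its children
    profiles: dict[int, tuple[list[str], list[str]]] = {}  # node id -> (ids, rows)
    for node in guide.postorder():
        if node.is_leaf:
            rec = by_id[node.name]
            profiles[id(node)] = ([rec.id], [rec.sequence])
        else:
            ids, rows = profiles.pop(id(node.children[0]))
            for child in node.children[1:]:
                cids, crows = profiles.pop(id(child))
                rows, crows = _profile_align(rows, crows, scheme)
                ids = ids + cids
                rows = rows + crows
            profiles[id(node)] = (ids, rows)

    ids, rows = profiles[id(guide.root)]
    order = {rid: k for k, rid in enumerate(ids)}
    final_rows = [rows[order[r.id]] for r in recs]
    return MultipleAlignment(row_ids=[r.id for r in recs], rows=final_rows)
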