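"""Protein sequence records, FASTA I/O and redundancy reduction.

Sequences are restricted to the 20 standard residues plus ``X`` (unknown).
Redundancy reduction comes in two flavours: exact-duplicate removal
(:func:`dedup_exact`, the default) and greedy identity clustering
(:func:`cluster_identity`) for near-duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError, InvalidArgumentError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AA_ALPHABET + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence with provenance."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise InvalidArgumentError("record id must be non-empty")
        if not self.sequence:
            raise InvalidArgumentError(f"record '{self.id}': sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise InvalidArgumentError(
                f"record '{self.id}': illegal residue(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceFamily:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord]
    provenance: str = ""
    #: kept_id -> ids of verbatim duplicates removed in its favour (set by dedup)
    dedup_report: dict[str, list[str]] | None = field(default=None, repr=False)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record id(s): {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path, *, on_nonstandard: str = "error") -> SequenceFamily:
    """Read a protein FASTA file into a :class:`SequenceFamily`.

    Parameters
    ----------
    path
        FASTA file path.
    on_nonstandard
        ``"error"`` rejects residues outside the 20 standard + X;
        ``"mask"`` maps them to ``X``.

    Raises
    ------
    FormatError
        Empty file, duplicate ids or illegal characters.
    """
    if on_nonstandard not in ("error", "mask"):
        raise InvalidArgumentError(f"on_nonstandard must be 'error' or 'mask', got {on_nonstandard!r}")
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper().replace("*", "")
        if on_nonstandard == "mask":
            seq = "".join(c if c in VALID_RESIDUES else "X" for c in seq)
        else:
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise FormatError(
                    f"{path}: record {i} ('{rec.id}') has illegal residue(s) {sorted(bad)}"
                )
        if not seq:
            raise FormatError(f"{path}: record {i} ('{rec.id}') has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    try:
        return SequenceFamily(records=records, provenance=f"read_fasta({path})")
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_fasta(family: SequenceFamily, path, wrap: int = 60) -> None:
    """Write a family as FASTA; round-trips with :func:`read_fasta`."""
    if family.n == 0:
        raise DataError("refusing to write an empty family")
    if wrap < 1:
        raise InvalidArgumentError("wrap must be >= 1")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in family
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


def dedup_exact(family: SequenceFamily) -> SequenceFamily:
    """Drop later verbatim duplicates, keeping first occurrences in order.

    The returned family carries a ``dedup_report`` mapping each kept id to
    the ids removed in its favour.
    """
    seen: dict[str, str] = {}  # sequence -> kept id
    kept: list[ProteinRecord] = []
    report: dict[str, list[str]] = {}
    for rec in family:
        keeper = seen.get(rec.sequence)
        if keeper is None:
            seen[rec.sequence] = rec.id
            kept.append(rec)
            report[rec.id] = []
        else:
            report[keeper].append(rec.id)
    return SequenceFamily(
        records=kept,
        provenance=f"dedup_exact({family.provenance or 'family'})",
        dedup_report=report,
    )


def cluster_identity(family: SequenceFamily, threshold: float,
                     scheme=None) -> SequenceFamily:
    """Greedy identity clustering in input order; returns representatives.

    A record joins the first existing cluster whose representative shares
    >= ``threshold`` identity over a pairwise global alignment (identity
    counted over columns excluding terminal gaps). At ``threshold == 1.0``
    this coincides with :func:`dedup_exact`.
    """
    if not (0 < threshold <= 1):
        raise InvalidArgumentError(f"threshold must be in (0, 1], got {threshold}")
    from .phylo.pairwise import ScoringScheme, global_align, alignment_identity

    if scheme is None:
        scheme = ScoringScheme.blosum62()
    reps: list[ProteinRecord] = []
    report: dict[str, list[str]] = {}
    for rec in family:
        placed = False
        for rep in reps:
            if rec.sequence == rep.sequence:
                ident = 1.0
            else:
                aln = global_align(rep.sequence, rec.sequence, scheme)
                ident = alignment_identity(aln.aligned_a, aln.aligned_b)
                # nested sequences can score 1.0 with terminal gaps excluded;
                # distinct strings must stay below the exact-duplicate bound
                ident = min(ident, 1.0 - 1e-12)
            if ident >= threshold:
                report[rep.id].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            report[rec.id] = []
    return SequenceFamily(
        records=reps,
        provenance=f"cluster_identity(threshold={threshold})",
        dedup_report=report,
    )


def write_dedup_report(family: SequenceFamily, path) -> None:
    """TSV of dedup decisions: kept_id <tab> comma-joined removed ids."""
    if family.dedup_report is None:
        raise DataError("family carries no dedup report")
    with open(path, "w") as fh:
        fh.write("kept_id\tremoved_ids\n")
        for kept, removed in family.dedup_report.items():
            fh.write(f"{kept}\t{','.join(removed)}\n")
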