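"""Terminal k-mer profiling, consensus calling and degron-likeness scores.

Frequencies are computed on unaligned terminal windows (the last k
residues of each sequence), not on alignment columns. A sequence is
excluded all-or-none: too short for the window, or containing an X
inside it. The consensus takes the modal residue per position; a
position counts as conserved only when its top frequency strictly
exceeds the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np

from .errors import DataError, InvalidArgumentError
from .seqio import AA_ALPHABET, ProteinRecord, SequenceFamily

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Residues over-represented in C-terminal proteolysis signals.
DEGRON_COMPOSITION_SET = frozenset("LAVS")


def reference_motifs() -> dict[str, str]:
    """The bundled catalogue of reference degron motifs."""
    text = resources.files("ctdegron.data").joinpath("reference_degrons.json").read_text()
    return json.loads(text)


class CtermWindow(NamedTuple):
    """Result of terminal window extraction; exactly one field is set."""

    kmer: str | None
    exclusion_reason: str | None


def extract_cterm(record: ProteinRecord, k: int = 10) -> CtermWindow:
    """Last k residues of a record, or an exclusion with its reason."""
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    if len(record.sequence) < k:
        return CtermWindow(None, "too short")
    window = record.sequence[-k:]
    if "X" in window:
        return CtermWindow(None, "X in terminal window")
    return CtermWindow(window, None)


@dataclass
class TerminalProfile:
    """Per-position residue counts/frequencies over terminal k-mers.

    Positions are numbered 1..k from the N-side of the window (position k
    is the C-terminal residue). ``counts`` and ``frequencies`` are
    (k x 20) arrays over the alphabet ``ACDEFGHIKLMNPQRSTVWY``.
    """

    k: int
    counts: np.ndarray
    n_sequences: int
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def frequency(self, position: int, residue: str) -> float:
        """Frequency of ``residue`` at 1-based window position."""
        return float(self.frequencies[position - 1, _AA_INDEX[residue]])

    def to_tsv(self, path) -> None:
        """Percent table to 2 decimals: rows positions, columns residues."""
        freq = self.frequencies * 100.0
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(AA_ALPHABET) + "\n")
            for i in range(self.k):
                row = "\t".join(f"{freq[i, a]:.2f}" for a in range(20))
                fh.write(f"{i + 1}\t{row}\n")

    def text_logo(self, max_height: int = 10) -> str:
        """Plain-text logo: per position, letters stacked by frequency."""
        freq = self.frequencies
        cols = []
        for i in range(self.k):
            order = sorted(range(20), key=lambda a: (-freq[i, a], AA_ALPHABET[a]))
            stack = ""
            for a in order:
                reps = int(round(freq[i, a] * max_height))
                stack += AA_ALPHABET[a] * reps
            cols.append(stack[:max_height].ljust(max_height, "."))
        lines = []
        for level in range(max_height):
            lines.append("".join(col[level] for col in cols))
        lines.append("-" * self.k)
        lines.append("".join(str((i + 1) % 10) for i in range(self.k)))
        return "\n".join(lines)


def positional_frequency(family: SequenceFamily, k: int = 10) -> TerminalProfile:
    """Count residues per position over the terminal k-mers of a family.

    Raises :class:`DataError` when no record is includable.
    """
    counts = np.zeros((k, 20), dtype=int)
    excluded: list[tuple[str, str]] = []
    n_included = 0
    for rec in family:
        kmer, reason = extract_cterm(rec, k)
        if kmer is None:
            excluded.append((rec.id, reason))
            continue
        n_included += 1
        for i, aa in enumerate(kmer):
            counts[i, _AA_INDEX[aa]] += 1
    if n_included == 0:
        raise DataError(
            f"no includable records for terminal profiling (k={k}; "
            f"{len(excluded)} excluded)"
        )
    return TerminalProfile(k=k, counts=counts, n_sequences=n_included,
                           excluded=excluded)


@dataclass(frozen=True)
class ConsensusMotif:
    residues: str
    per_position_frequency: tuple[float, ...]
    conserved_flags: tuple[bool, ...]
    ambiguity_flags: tuple[bool, ...]
    threshold: float

    @property
    def n_conserved(self) -> int:
        return sum(self.conserved_flags)


def consensus_motif(profile: TerminalProfile, threshold: float = 0.5) -> ConsensusMotif:
    """Modal residue per position; ties resolved alphabetically and flagged."""
    if not (0 <= threshold < 1):
        raise InvalidArgumentError(f"threshold must be in [0, 1), got {threshold}")
    residues = []
    freqs = []
    conserved = []
    ambiguous = []
    counts = profile.counts
    for i in range(profile.k):
        top = counts[i].max()
        winners = [a for a in range(20) if counts[i, a] == top]
        residues.append(AA_ALPHABET[winners[0]])  # alphabet order is lexicographic
        f = top / profile.n_sequences
        freqs.append(float(f))
        conserved.append(bool(f > threshold))
        ambiguous.append(len(winners) > 1)
    return ConsensusMotif(
        residues="".join(residues),
        per_position_frequency=tuple(freqs),
        conserved_flags=tuple(conserved),
        ambiguity_flags=tuple(ambiguous),
        threshold=threshold,
    )


def right_anchored_identity(query: str, reference: str) -> float:
    """Identity of two motifs aligned at their C-terminal ends.

    Matches are counted over the last ``min(len(query), len(reference))``
    positions and divided by that shorter length.
    """
    if not query or not reference:
        raise InvalidArgumentError("motifs must be non-empty")
    L = min(len(query), len(reference))
    q, r = query[-L:], reference[-L:]
    return sum(1 for x, y in zip(q, r) if x == y) / L


def composition_score(motif: str,
                      residue_set: frozenset[str] = DEGRON_COMPOSITION_SET) -> float:
    """Fraction of motif residues belonging to ``residue_set``."""
    if not motif:
        raise InvalidArgumentError("motif must be non-empty")
    return sum(1 for aa in motif if aa in residue_set) / len(motif)


def dipeptide_present(motif: str, dipeptide: str) -> tuple[bool, list[int]]:
    """All 1-based start positions of ``dipeptide`` in ``motif`` (may overlap)."""
    if len(dipeptide) != 2:
        raise InvalidArgumentError("dipeptide must have length 2")
    positions = [i + 1 for i in range(len(motif) - 1)
                 if motif[i:i + 2] == dipeptide]
    return bool(positions), positions


@dataclass(frozen=True)
class DegronScore:
    """Similarity of a query motif to a named reference catalogue."""

    query: str
    right_anchored_identity: dict[str, float]
    composition_score: float
    reference_set: dict[str, str]


def score_degron(query: str, references: dict[str, str] | None = None) -> DegronScore:
    if references is None:
        references = reference_motifs()
    return DegronScore(
        query=query,
        right_anchored_identity={
            name: right_anchored_identity(query, ref)
            for name, ref in references.items()
        },
        composition_score=composition_score(query),
        reference_set=dict(references),
    )
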