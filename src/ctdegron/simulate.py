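"""Ground-truth generators: sequence families with a planted C-terminal
motif under reduced substitution pressure, and reporter time courses with
known synthesis/decay kinetics.

Families evolve along a random join (Yule-like) topology with exponential
branch lengths under a uniform-replacement substitution model: per site
and branch, a substitution fires with probability 1 - exp(-rate * length)
and redraws the residue uniformly from the 20 standard amino acids. The
last ``len(planted_motif)`` positions use ``motif_sub_rate`` instead of
``body_sub_rate``, which plants a differentially conserved terminal block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .phylo.tree import PhyloTree, TreeNode
from .seqio import AA_ALPHABET, ProteinRecord, SequenceFamily

#: Mean of the exponential draw used for branch lengths.
BRANCH_LENGTH_MEAN = 0.2


@dataclass(frozen=True)
class FamilySimConfig:
    n_taxa: int
    root_length: int = 120
    planted_motif: str = "RMSAYGLAAA"
    body_sub_rate: float = 1.0
    motif_sub_rate: float = 0.02
    n_exact_duplicates: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise InvalidArgumentError(f"n_taxa must be >= 3, got {self.n_taxa}")
        if self.root_length < len(self.planted_motif):
            raise InvalidArgumentError(
                f"root_length {self.root_length} shorter than planted motif "
                f"({len(self.planted_motif)} residues)"
            )
        if self.body_sub_rate < 0 or self.motif_sub_rate < 0:
            raise InvalidArgumentError("substitution rates must be >= 0")
        if self.n_exact_duplicates < 0:
            raise InvalidArgumentError("n_exact_duplicates must be >= 0")
        if any(c not in AA_ALPHABET for c in self.planted_motif):
            raise InvalidArgumentError("planted motif must use the 20 standard residues")


def simulate_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Random unrooted binary tree with exponential branch lengths.

    Topology arises from uniformly random pairwise joins (equivalent in
    distribution to a Yule labeled shape); branch lengths are iid
    Exponential(mean=0.2). Deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise InvalidArgumentError(f"n_taxa must be >= 3, got {n_taxa}")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    lineages = [TreeNode(name=f"t{i + 1:0{width}d}") for i in range(n_taxa)]

    def draw_length() -> float:
        return float(max(rng.exponential(BRANCH_LENGTH_MEAN), 1e-6))

    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = TreeNode()
        a.length = draw_length()
        b.length = draw_length()
        parent.add_child(a)
        parent.add_child(b)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)

    root = TreeNode()
    for node in lineages:
        node.length = draw_length()
        root.add_child(node)
    return PhyloTree(root)


def evolve_family(tree: PhyloTree, cfg: FamilySimConfig) -> SequenceFamily:
    """Evolve a root sequence down a tree; returns leaves plus duplicates.

    The root sequence is random with ``planted_motif`` occupying its last
    positions. Each leaf becomes a record; ``n_exact_duplicates`` verbatim
    copies of randomly chosen leaves are appended with ``_dupN`` ids.
    Record descriptions carry the planted motif as ground-truth metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.planted_motif)
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

    body_len = cfg.root_length - k
    root_seq = np.concatenate([
        rng.choice(aa, size=body_len),
        np.frombuffer(cfg.planted_motif.encode(), dtype=np.uint8),
    ])

    site_rates = np.full(cfg.root_length, cfg.body_sub_rate)
    site_rates[-k:] = cfg.motif_sub_rate

    leaf_seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p_sub = 1.0 - np.exp(-site_rates * child.length)
            hits = rng.random(cfg.root_length) < p_sub
            child_seq = seq.copy()
            if hits.any():
                child_seq[hits] = rng.choice(aa, size=int(hits.sum()))
            if child.is_leaf:
                leaf_seqs[child.name] = child_seq.tobytes().decode()
            else:
                descend(child, child_seq)

    descend(tree.root, root_seq)

    meta = f"planted_motif={cfg.planted_motif}"
    records = [
        ProteinRecord(id=name, sequence=leaf_seqs[name], description=meta)
        for name in sorted(leaf_seqs)
    ]
    if cfg.n_exact_duplicates:
        sources = rng.choice(len(records), size=cfg.n_exact_duplicates, replace=True)
        for d, src in enumerate(sources, start=1):
            origin = records[src]
            records.append(ProteinRecord(
                id=f"{origin.id}_dup{d}",
                sequence=origin.sequence,
                description=f"{meta} duplicate_of={origin.id}",
            ))
    return SequenceFamily(records=records,
                          provenance=f"evolve_family(seed={cfg.seed})")


def write_ground_truth(cfg: FamilySimConfig, path) -> None:
    """JSON sidecar recording the simulation's ground truth."""
    with open(path, "w") as fh:
        json.dump({
            "planted_motif": cfg.planted_motif,
            "n_taxa": cfg.n_taxa,
            "body_sub_rate": cfg.body_sub_rate,
            "motif_sub_rate": cfg.motif_sub_rate,
            "n_exact_duplicates": cfg.n_exact_duplicates,
            "seed": cfg.seed,
        }, fh, indent=2)
        fh.write("\n")


@dataclass(frozen=True)
class TimeCourseSimConfig:
    """Reporter kinetics: dF/dt = synthesis_rate - decay_rate * F, with
    logistic OD600 growth and multiplicative lognormal noise."""

    t_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 31))
    f0: float = 100.0
    synthesis_rate: float = 50.0
    decay_rate: float = 0.2
    od_carrying_capacity: float = 2.0
    od_rate: float = 0.5
    od_midpoint: float = 6.0
    noise_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("t_grid must be strictly increasing, length >= 2")
        object.__setattr__(self, "t_grid", tuple(float(x) for x in t))
        if self.decay_rate < 0:
            raise InvalidArgumentError("decay_rate must be >= 0")
        if self.noise_cv < 0:
            raise InvalidArgumentError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")
        if self.f0 < 0 or self.synthesis_rate < 0:
            raise InvalidArgumentError("f0 and synthesis_rate must be >= 0")
        if self.od_carrying_capacity <= 0:
            raise InvalidArgumentError("od_carrying_capacity must be > 0")


def _fluorescence(cfg: TimeCourseSimConfig, t: np.ndarray, decay: float) -> np.ndarray:
    s, f0 = cfg.synthesis_rate, cfg.f0
    if decay > 0:
        steady = s / decay
        return steady + (f0 - steady) * np.exp(-decay * t)
    return f0 + s * t


def _od(cfg: TimeCourseSimConfig, t: np.ndarray) -> np.ndarray:
    return cfg.od_carrying_capacity / (
        1.0 + np.exp(-cfg.od_rate * (t - cfg.od_midpoint))
    )


def simulate_timecourse(cfg: TimeCourseSimConfig, tagged: bool,
                        condition: str | None = None,
                        genotype: str = "WT",
                        decay_scale: float = 1.0) -> "TimeCourse":
    """One reporter time course as a tidy frame.

    Columns: time_h, fluorescence, od600, condition, genotype, replicate.
    Tagged runs decay at ``cfg.decay_rate * decay_scale``; untagged runs
    use zero decay but share synthesis and OD parameters, so the
    percent-of-control readout isolates degradation. Noise is
    multiplicative lognormal with the configured CV (mean 1),
    independently on fluorescence and OD.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.t_grid)
    decay = cfg.decay_rate * decay_scale if tagged else 0.0
    f_true = _fluorescence(cfg, t, decay)
    od_true = _od(cfg, t)
    if condition is None:
        condition = "tagged" if tagged else "untagged-control"

    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv ** 2)) if cfg.noise_cv > 0 else 0.0
    frames = []
    for rep in range(1, cfg.n_replicates + 1):
        if sigma > 0:
            f_noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=len(t)))
            od_noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=len(t)))
        else:
            f_noise = od_noise = np.ones(len(t))
        frames.append(pd.DataFrame({
            "time_h": t,
            "fluorescence": f_true * f_noise,
            "od600": od_true * od_noise,
            "condition": condition,
            "genotype": genotype,
            "replicate": rep,
        }))
    from .assay import TimeCourse

    return TimeCourse(pd.concat(frames, ignore_index=True))


def simulate_assay_dataset(cfg: TimeCourseSimConfig,
                           genotype_decay_scales: dict[str, float] | None = None,
                           tagged_condition: str = "tagged") -> "TimeCourse":
    """Paired tagged/untagged courses, optionally across knockout genotypes.

    ``genotype_decay_scales`` maps genotype labels to multipliers on the
    tagged decay rate (protease knockouts slow degradation). Each
    genotype gets its own derived seed for independent noise.
    """
    from .assay import TimeCourse

    if genotype_decay_scales is None:
        genotype_decay_scales = {"WT": 1.0}
    frames = []
    for g_i, (genotype, scale) in enumerate(sorted(genotype_decay_scales.items())):
        sub = TimeCourseSimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * g_i})
        frames.append(simulate_timecourse(sub, tagged=False, genotype=genotype).df)
        sub2 = TimeCourseSimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * g_i + 500})
        frames.append(simulate_timecourse(sub2, tagged=True,
                                          condition=tagged_condition,
                                          genotype=genotype, decay_scale=scale).df)
    return TimeCourse(pd.concat(frames, ignore_index=True))


# re-exported field ordering for TSV interchange
TIMECOURSE_COLUMNS = ["time_h", "fluorescence", "od600",
                      "condition", "genotype", "replicate"]
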