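"""End-to-end orchestration: sequences -> dedup -> MSA -> NJ+bootstrap ->
representatives -> terminal profile -> consensus -> degron scores, and the
parallel time-course -> degradation-report track. All stage outputs are
written as plain-text artifacts and summarized in a machine-readable
RunReport."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assay import (CONTROL_CONDITION, DegradationResult, TimeCourse,
                    quantify_degradation, recovery_index)
from .errors import ConfigError, CtdegronError, PipelineStageError
from .motif import consensus_motif, positional_frequency, score_degron
from .phylo import (ScoringScheme, alignment_distance_matrix,
                    bootstrap_support, progressive_msa,
                    select_representatives)
from .seqio import cluster_identity, dedup_exact, read_fasta, write_fasta

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str | None = None
    timecourse_tsv: str | None = None
    outdir: str = "ctdegron_out"
    k: int = 10
    conservation_threshold: float = 0.5
    n_bootstrap: int = 100
    n_representatives: int = 8
    dedup_mode: str = "exact"  # "exact" | "identity"
    dedup_threshold: float = 1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    endpoint_time: float = 25.0
    od_floor: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0 <= self.conservation_threshold < 1):
            raise ConfigError("conservation_threshold must be in [0, 1)")
        if self.dedup_mode not in ("exact", "identity"):
            raise ConfigError(f"unknown dedup_mode {self.dedup_mode!r}")
        if not (0 < self.dedup_threshold <= 1):
            raise ConfigError("dedup_threshold must be in (0, 1]")
        if self.n_bootstrap < 1 or self.n_representatives < 1:
            raise ConfigError("n_bootstrap and n_representatives must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigError(f"config is not valid JSON: {e}") from None
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def fingerprint(self) -> str:
        digest = hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
        return f"ctdegron-{__version__}:{digest}"


@dataclass
class RunReport:
    fingerprint: str
    counts: dict = field(default_factory=dict)
    consensus: str | None = None
    conserved_flags: list[bool] | None = None
    n_conserved: int | None = None
    degron_scores: dict | None = None
    representatives: list[str] | None = None
    tree_file: str | None = None
    artifacts: dict = field(default_factory=dict)
    degradation: list[dict] | None = None
    recovery: list[dict] | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _stage(name: str):
    """Decorator-free stage wrapper: reraise with stage context."""
    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_sequence_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full sequence-analysis track and write all artifacts."""
    if not config.fasta:
        raise ConfigError("config.fasta is required for the sequence pipeline")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(fingerprint=config.fingerprint())
    scheme = ScoringScheme.blosum62(gap_open=config.gap_open,
                                    gap_extend=config.gap_extend)

    with _stage("read-fasta"):
        family = read_fasta(config.fasta)
        report.counts["input"] = family.n

    with _stage("dedup"):
        if config.dedup_mode == "exact":
            family = dedup_exact(family)
        else:
            family = cluster_identity(family, config.dedup_threshold, scheme)
        report.counts["after_dedup"] = family.n
        deduped_path = outdir / "deduped.fasta"
        write_fasta(family, deduped_path)
        report.artifacts["deduped_fasta"] = str(deduped_path)

    with _stage("align"):
        aln = progressive_msa(family, scheme)
        aln_path = outdir / "alignment.fasta"
        aln.write_fasta(aln_path)
        report.artifacts["alignment_fasta"] = str(aln_path)

    with _stage("tree"):
        if family.n >= 4:
            tree = bootstrap_support(aln, n_replicates=config.n_bootstrap,
                                     seed=config.seed)
        else:
            from .phylo import tree_from_alignment

            tree = tree_from_alignment(aln)
        tree_path = outdir / "tree.nwk"
        tree.write_newick(tree_path)
        report.tree_file = str(tree_path)
        report.artifacts["tree_newick"] = str(tree_path)

    with _stage("representatives"):
        dm = alignment_distance_matrix(aln)
        n_groups = min(config.n_representatives, family.n)
        report.representatives = select_representatives(tree, dm, n_groups)

    with _stage("profile"):
        profile = positional_frequency(family, config.k)
        report.counts["profiled"] = profile.n_sequences
        report.counts["excluded_from_profile"] = len(profile.excluded)
        profile_path = outdir / "terminal_profile.tsv"
        profile.to_tsv(profile_path)
        report.artifacts["profile_tsv"] = str(profile_path)
        logo_path = outdir / "terminal_logo.txt"
        logo_path.write_text(profile.text_logo() + "\n")
        report.artifacts["logo_txt"] = str(logo_path)

    with _stage("consensus"):
        cons = consensus_motif(profile, config.conservation_threshold)
        report.consensus = cons.residues
        report.conserved_flags = list(cons.conserved_flags)
        report.n_conserved = cons.n_conserved

    with _stage("score"):
        score = score_degron(cons.residues)
        report.degron_scores = {
            "right_anchored_identity": score.right_anchored_identity,
            "composition_score": score.composition_score,
        }
        consensus_path = outdir / "consensus.json"
        consensus_path.write_text(json.dumps({
            "consensus": cons.residues,
            "per_position_frequency": list(cons.per_position_frequency),
            "conserved_flags": list(cons.conserved_flags),
            "ambiguity_flags": list(cons.ambiguity_flags),
            "threshold": cons.threshold,
            "scores": report.degron_scores,
        }, indent=2) + "\n")
        report.artifacts["consensus_json"] = str(consensus_path)

    report.write(outdir / "run_report.json")
    report.artifacts["run_report"] = str(outdir / "run_report.json")
    return report


def run_assay_pipeline(config: PipelineConfig) -> RunReport:
    """Quantify degradation per (condition, genotype) against untagged controls."""
    if not config.timecourse_tsv:
        raise ConfigError("config.timecourse_tsv is required for the assay pipeline")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(fingerprint=config.fingerprint())

    with _stage("read-timecourse"):
        tc = TimeCourse.read_tsv(config.timecourse_tsv)

    with _stage("quantify"):
        results: list[DegradationResult] = []
        for genotype in tc.genotypes():
            try:
                control = tc.subset(CONTROL_CONDITION, genotype)
            except CtdegronError:
                continue
            for condition in tc.conditions():
                if condition == CONTROL_CONDITION:
                    continue
                try:
                    tagged = tc.subset(condition, genotype)
                except CtdegronError:
                    continue
                results.append(quantify_degradation(
                    tagged, control, config.endpoint_time, config.od_floor))
        report.degradation = [
            {
                "condition": r.condition,
                "genotype": r.genotype,
                "endpoint_time": r.endpoint_time,
                "percent_of_control": r.percent_of_control,
                "degradation_percent": r.degradation_percent,
                "decay_rate_estimate": r.decay_rate_estimate,
            }
            for r in results
        ]

    with _stage("recovery"):
        by_key = {(r.condition, r.genotype): r for r in results}
        recov = []
        for (cond, geno), r in by_key.items():
            wt = by_key.get((cond, "WT"))
            if geno == "WT" or wt is None:
                continue
            recov.append({
                "condition": cond,
                "genotype": geno,
                "recovery_points": recovery_index(r, wt),
            })
        report.recovery = recov

    table_path = outdir / "degradation.json"
    table_path.write_text(json.dumps({
        "degradation": report.degradation,
        "recovery": report.recovery,
    }, indent=2) + "\n")
    report.artifacts["degradation_json"] = str(table_path)
    report.write(outdir / "assay_report.json")
    return report
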