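"""Pipeline orchestration: configuration, stage wiring, and artifacts.

Three entry points mirror the analysis workflow:

* :func:`run_simulate` — build a synthetic GC-rich gene and a read set
  with machine-readable truth (FASTA/FASTQ + BED + TSV).
* :func:`run_profile` — recruit reads against a query, compute the
  coverage report (expected vs. observed bases, depletion, patchiness,
  error rates) and the non-B annotation (BED + summary).
* :func:`run_reconstruct` — recruit, orient, build the majority-vote
  consensus, infer exon/intron structure from a cDNA, and report stats.

Every run writes a ``manifest.json`` recording the package version, seed
and thresholds; outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consensus import (build_consensus, infer_gene_structure, model_stats,
                        orient_reads, write_column_tsv, write_consensus_fasta,
                        write_structure_gff3, StructureUndeterminedError)
from .coverage import coverage_report, write_bedgraph
from .motifs import nonb_annotation, summarize_sequences, write_motif_bed
from .recruit import recruit_reads, write_alignments_tsv
from .simulate import (SimulationTruth, generate_gene, simulate_long_reads,
                       write_gene, write_reads_fasta, write_reads_fastq,
                       write_truth_tsv)

__all__ = ["PipelineConfig", "ConfigError", "MissingInputError",
           "run_simulate", "run_profile", "run_reconstruct"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class MissingInputError(FileNotFoundError):
    """A configured input path does not exist."""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one serialisable object."""

    # inputs
    query: str | None = None
    cdna: str | None = None
    reads: str | None = None
    outdir: str = "nonbcov_out"
    # dataset bookkeeping
    dataset_depth: float = 60.0
    copy_number: int = 1
    # recruitment
    k: int = 13
    min_read_len: int = 400
    min_aln_len: int = 400
    min_identity: float = 70.0
    # consensus
    min_depth: int = 5
    max_iter: int = 5
    # motif scanning
    g4_max_loop: int = 12
    tandem_max_period: int = 20
    tandem_min_copies: int = 3
    tandem_min_len: int = 12
    dyad_min_arm: int = 6
    dyad_max_loop: int = 50
    dyad_max_arm_mismatch: int = 1
    # simulation
    n_exons: int = 2
    exon_len: int = 1000
    intron_motifs: list[str] = field(default_factory=lambda: ["TTGGGGGGG"])
    intron_copies: list[int] = field(default_factory=lambda: [150])
    exon_gc: float = 65.0
    depletion: float = 0.9
    error_rate: float = 0.13
    nonb_error_rate: float = 0.20
    read_len_mean: int = 1000
    flank: int = 2000
    fastq: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.k < 8:
            raise ConfigError("k must be >= 8")
        if self.min_read_len < 0 or self.min_aln_len < 0 or self.min_identity < 0:
            raise ConfigError("recruitment thresholds must be >= 0")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if self.dataset_depth <= 0 or self.copy_number < 1:
            raise ConfigError("dataset_depth must be > 0 and copy_number >= 1")
        if not 0 <= self.depletion <= 1:
            raise ConfigError("depletion must be in [0, 1]")
        if self.dyad_min_arm < 3:
            raise ConfigError("dyad_min_arm must be >= 3")
        return self

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    # -- helpers ------------------------------------------------------------

    def scan_kwargs(self) -> dict:
        return {
            "g4_kwargs": {"max_loop": self.g4_max_loop},
            "tandem_kwargs": {"max_period": self.tandem_max_period,
                              "min_copies": self.tandem_min_copies,
                              "min_len": self.tandem_min_len},
            "dyad_kwargs": {"min_arm": self.dyad_min_arm,
                            "max_loop": self.dyad_max_loop,
                            "max_arm_mismatch": self.dyad_max_arm_mismatch},
        }


def _read_fasta(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    p = Path(path)
    if not p.exists():
        raise MissingInputError(str(p))
    fmt = "fastq" if p.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), fmt)]


def _manifest(cfg: PipelineConfig, outdir: Path, stage: str,
              extra: dict | None = None) -> None:
    data = {"tool": "nonbcov", "version": __version__, "stage": stage,
            "config": dataclasses.asdict(cfg)}
    if extra:
        data.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate a synthetic gene plus long reads and write the bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = generate_gene(cfg.n_exons, cfg.exon_len, cfg.intron_motifs,
                         cfg.intron_copies, cfg.exon_gc, cfg.seed)
    truth = SimulationTruth(depletion=cfg.depletion, error_rate=cfg.error_rate,
                            nonb_error_rate=cfg.nonb_error_rate,
                            depth=cfg.dataset_depth, seed=cfg.seed)
    dataset = simulate_long_reads(gene, truth, read_len_mean=cfg.read_len_mean,
                                  flank=cfg.flank)
    write_gene(gene, outdir / "gene.fasta", outdir / "gene.bed")
    if cfg.fastq:
        write_reads_fastq(dataset.reads, outdir / "reads.fastq")
    else:
        write_reads_fasta(dataset.reads, outdir / "reads.fasta")
    write_truth_tsv(dataset, outdir / "truth.tsv")
    _manifest(cfg, outdir, "simulate", {
        "n_reads": len(dataset.reads), "n_candidates": dataset.n_candidates,
        "gene_length": len(gene), "gene_gc": gene.gc_percent})
    return {"gene": gene, "dataset": dataset, "outdir": outdir}


def run_profile(cfg: PipelineConfig) -> dict:
    """Recruit reads against the query and report coverage + non-B tracks."""
    cfg.validate()
    if cfg.query is None or cfg.reads is None:
        raise ConfigError("profile needs query and reads paths")
    query_id, query_seq = _read_fasta(cfg.query)[0]
    reads = _read_fasta(cfg.reads)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignments = recruit_reads(query_seq, reads, k=cfg.k,
                               min_read_len=cfg.min_read_len,
                               min_aln_len=cfg.min_aln_len,
                               min_identity=cfg.min_identity)
    report = coverage_report(query_id, len(query_seq), alignments,
                             copy_number=cfg.copy_number,
                             dataset_depth=cfg.dataset_depth)
    ann = nonb_annotation(query_seq, **cfg.scan_kwargs())
    write_alignments_tsv(alignments, outdir / "alignments.tsv")
    report.to_json(outdir / "coverage.json")
    report.to_tsv(outdir / "coverage.tsv")
    write_bedgraph(report.depth, query_id, outdir / "depth.bedgraph")
    write_motif_bed(ann.hits, query_id, outdir / "nonb.bed")
    summarize_sequences([(query_id, query_seq)], **cfg.scan_kwargs()) \
        .to_csv(outdir / "summary.tsv", sep="\t", index=False)
    _manifest(cfg, outdir, "profile", {
        "n_alignments": len(alignments),
        "depletion_percent": report.depletion_percent,
        "patchiness": report.patchiness,
        "nonb_fraction": ann.fraction})
    return {"report": report, "annotation": ann, "alignments": alignments,
            "outdir": outdir}


def run_reconstruct(cfg: PipelineConfig) -> dict:
    """Recruit, orient, build the consensus model and infer structure."""
    cfg.validate()
    if cfg.query is None or cfg.reads is None:
        raise ConfigError("reconstruct needs query (seed model) and reads")
    query_id, query_seq = _read_fasta(cfg.query)[0]
    reads = _read_fasta(cfg.reads)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignments = recruit_reads(query_seq, reads, k=cfg.k,
                               min_read_len=cfg.min_read_len,
                               min_aln_len=cfg.min_aln_len,
                               min_identity=cfg.min_identity)
    oriented = orient_reads(alignments, reads) if alignments else {}
    model = build_consensus(query_seq, oriented, min_depth=cfg.min_depth,
                            max_iter=cfg.max_iter)
    structure = None
    if cfg.cdna is not None:
        _, cdna_seq = _read_fasta(cfg.cdna)[0]
        try:
            structure = infer_gene_structure(model.sequence, cdna_seq)
            model.exons = structure.exons
            model.splice_dinucleotides = structure.splice_dinucleotides
        except StructureUndeterminedError:
            structure = None
    stats = model_stats(model, structure)
    write_consensus_fasta(model, f"{query_id}_consensus",
                          outdir / "consensus.fasta")
    write_column_tsv(model, outdir / "columns.tsv")
    if structure is not None:
        write_structure_gff3(structure, f"{query_id}_consensus",
                             outdir / "structure.gff3")
    with open(outdir / "stats.json", "w") as fh:
        json.dump(dataclasses.asdict(stats), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _manifest(cfg, outdir, "reconstruct", {
        "n_alignments": len(alignments), "n_reads_used": len(oriented),
        "model_length": len(model), "n_fraction": model.n_fraction,
        "converged": model.converged})
    return {"model": model, "structure": structure, "stats": stats,
            "alignments": alignments, "outdir": outdir}
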