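"""Consensus gene-model reconstruction from recruited noisy long reads.

Reads are oriented to the query strand, aligned one by one to an evolving
model (seeded by a cDNA or any draft sequence), and a per-column majority
vote is taken: the plurality base wins (ties broken by the fixed order
A < C < G < T, bases beating gaps), a gap majority deletes the column, and
a strict plurality of reads inserting the same base opens a new column.
Columns supported by fewer than ``min_depth`` reads are rendered as N —
the representation used for regions that cannot be aligned or are not
covered. Align-and-call is iterated until the model is stable.

Per-read alignment against the model uses unit-cost edit-distance
alignment (edlib, infix mode), the standard fast choice for noisy
long-read consensus.

A cDNA mapped back onto the genomic model yields the exon/intron structure
and the splice-site dinucleotides, with block edges slid by up to 5 bp to
expose GT/AG (canonical) and then CG/AG (the atypical variant reported for
avian leptin) before a junction is accepted as noncanonical.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import recruit as _recruit
from .motifs import gc_percent, nonb_annotation
from .recruit import ReadAlignment
from .seq import revcomp

__all__ = [
    "ConsensusModel",
    "GeneStructure",
    "StructureUndeterminedError",
    "orient_reads",
    "build_consensus",
    "global_identity",
    "infer_gene_structure",
    "model_stats",
    "write_consensus_fasta",
    "write_column_tsv",
    "write_structure_gff3",
]

_BASES = "ACGT"
_TIE_ORDER = {b: i for i, b in enumerate(_BASES)}
_CIG_RE = re.compile(r"(\d+)([=XIDM])")


class StructureUndeterminedError(RuntimeError):
    """Raised when a cDNA cannot be mapped onto the genomic model."""


@dataclass
class ConsensusModel:
    """Reconstructed gene sequence with per-column support.

    ``column_depth[i]`` counts reads contributing a non-gap character to
    column i; ``support[i]`` is the agreement fraction of the called
    character among those reads. Positions with depth below the build's
    ``min_depth`` are N.
    """

    sequence: str
    column_depth: np.ndarray = field(repr=False)
    support: np.ndarray = field(repr=False)
    min_depth: int = 5
    iterations: int = 0
    converged: bool = True
    exons: list[tuple[int, int]] | None = None
    splice_dinucleotides: list[tuple[str, str, str]] | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence) if self.sequence else 0.0


def orient_reads(alignments: list[ReadAlignment], reads) -> dict[str, str]:
    """Reverse-complement minus-strand reads so all are query-forward.

    ``reads`` is a mapping id -> sequence or iterable of (id, sequence).
    Reads without a retained alignment are skipped with a warning. When a
    read has several alignments the best-scoring one sets the orientation.
    """
    if not isinstance(reads, dict):
        reads = dict(reads)
    best: dict[str, ReadAlignment] = {}
    for a in alignments:
        if a.read_id not in best or a.score > best[a.read_id].score:
            best[a.read_id] = a
    oriented: dict[str, str] = {}
    for read_id, seq in reads.items():
        a = best.get(read_id)
        if a is None:
            warnings.warn(f"read {read_id} has no alignment; skipped")
            continue
        oriented[read_id] = revcomp(seq) if a.strand == "-" else seq
    return oriented


# ---------------------------------------------------------------------------
# Consensus building
# ---------------------------------------------------------------------------

def _align_to_model(read: str, model: str):
    """edlib infix alignment of a read to the model; returns
    (model_start, cigar) or None when edlib finds no alignment."""
    res = edlib.align(read, model, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0 = res["locations"][0][0]
    return t0, res["cigar"]


def _vote_pass(model: str, reads: dict[str, str], min_depth: int):
    """One align-and-call pass.

    Returns (work_sequence, masked_sequence, depth, support): the work
    sequence carries the majority base wherever any read covers a column
    (alignment in later passes uses it); the masked sequence additionally
    renders columns with non-gap depth below ``min_depth`` as N — the
    published representation of unalignable or uncovered stretches.
    """
    n = len(model)
    base_votes = np.zeros((n, 4), dtype=np.int64)
    gap_votes = np.zeros(n, dtype=np.int64)
    cover = np.zeros(n, dtype=np.int64)
    ins_votes: dict[int, dict[str, int]] = {}
    ins_cover = np.zeros(n + 1, dtype=np.int64)

    for seq in reads.values():
        hit = _align_to_model(seq, model)
        if hit is None:
            continue
        t, cigar = hit
        t0 = t
        q = 0
        for num, op in _CIG_RE.findall(cigar):
            ln = int(num)
            if op in "=XM":
                for j in range(ln):
                    ch = seq[q + j]
                    if ch in _TIE_ORDER:
                        base_votes[t + j, _TIE_ORDER[ch]] += 1
                t += ln
                q += ln
            elif op == "D":  # model bases absent from the read
                gap_votes[t:t + ln] += 1
                t += ln
            elif op == "I":  # read bases absent from the model
                ch = seq[q]
                if ch in _TIE_ORDER:
                    d = ins_votes.setdefault(t, {})
                    d[ch] = d.get(ch, 0) + 1
                q += ln
        cover[t0:t] += 1
        ins_cover[t0 + 1:t] += 1  # insertions need both neighbours covered

    work: list[str] = []
    masked: list[str] = []
    depth: list[int] = []
    support: list[float] = []

    def emit(ch: str, d: int, s: float) -> None:
        work.append(ch)
        masked.append(ch if (ch == "N" or d >= min_depth) else "N")
        depth.append(d)
        support.append(s)

    for i in range(n):
        if i > 0 and i in ins_votes and ins_cover[i] > 0:
            ch, cnt = max(ins_votes[i].items(),
                          key=lambda kv: (kv[1], -_TIE_ORDER[kv[0]]))
            if cnt > ins_cover[i] / 2:  # strict plurality opens a column
                emit(ch, int(cnt), cnt / ins_cover[i])
        if cover[i] == 0:
            emit("N", 0, 0.0)
            continue
        counts = base_votes[i]
        nongap = int(counts.sum())
        best_base = int(np.argmax(counts))  # argmax is leftmost: A<C<G<T
        if nongap == 0 or gap_votes[i] > counts[best_base]:
            continue  # gap majority deletes the column
        emit(_BASES[best_base], nongap, float(counts[best_base]) / nongap)
    return ("".join(work), "".join(masked),
            np.array(depth, dtype=np.int64), np.array(support))


def build_consensus(seed_model: str, oriented_reads, min_depth: int = 5,
                    max_iter: int = 5) -> ConsensusModel:
    """Iterative majority-vote consensus from oriented reads.

    Starts from ``seed_model``, aligns every read to the current model,
    calls each column, and repeats until the sequence is unchanged or
    ``max_iter`` passes have run. With no reads the seed is returned all-N
    (every position lacks read support).
    """
    if not seed_model:
        raise ValueError("seed_model must be non-empty")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    reads = dict(oriented_reads) if not isinstance(oriented_reads, dict) \
        else oriented_reads
    if not reads:
        n = len(seed_model)
        return ConsensusModel(sequence="N" * n,
                              column_depth=np.zeros(n, dtype=np.int64),
                              support=np.zeros(n), min_depth=min_depth,
                              iterations=0, converged=True)
    model = seed_model
    masked = model
    depth = np.zeros(len(model), dtype=np.int64)
    support = np.zeros(len(model))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_model, masked, depth, support = _vote_pass(model, reads, min_depth)
        if new_model == model:
            converged = True
            break
        model = new_model
    return ConsensusModel(sequence=masked, column_depth=depth,
                          support=support, min_depth=min_depth,
                          iterations=it, converged=converged)


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global (end-to-end) alignment of two
    sequences: match columns over all alignment columns."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = matches = 0
    for num, op in _CIG_RE.findall(res["cigar"]):
        cols += int(num)
        if op == "=":
            matches += int(num)
    return 100.0 * matches / cols


# ---------------------------------------------------------------------------
# Gene structure
# ---------------------------------------------------------------------------

@dataclass
class GeneStructure:
    """Exon/intron layout of a genomic model with splice classification."""

    exons: list[tuple[int, int]]
    # one entry per intron: (donor 2-mer, acceptor 2-mer, label)
    splice_dinucleotides: list[tuple[str, str, str]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]


def _classify(donor: str, acceptor: str) -> str:
    if (donor, acceptor) == ("GT", "AG"):
        return "canonical"
    if (donor, acceptor) == ("CG", "AG"):
        return "atypical-known"
    return "noncanonical"


def _slide_junction(g: str, e: int, s: int, max_shift: int = 5):
    """Slide intron [e, s) by up to ``max_shift`` bp to expose GT/AG, then
    CG/AG; a shift is legal only when the exon bases exchanged across the
    junction are identical (the alignment is ambiguous there)."""

    def legal(delta: int) -> bool:
        if delta > 0:
            return s + delta <= len(g) and g[e:e + delta] == g[s:s + delta]
        if delta < 0:
            return e + delta >= 0 and g[e + delta:e] == g[s + delta:s]
        return True

    deltas = [0]
    for d in range(1, max_shift + 1):
        deltas += [d, -d]
    for donor, acceptor in (("GT", "AG"), ("CG", "AG")):
        for d in deltas:
            e2, s2 = e + d, s + d
            if not legal(d) or s2 - e2 < 4:
                continue
            if g[e2:e2 + 2] == donor and g[s2 - 2:s2] == acceptor:
                return e2, s2
    return e, s


def _alignment_blocks(a: ReadAlignment, g: str, read: str, min_intron: int):
    """Split one cDNA-to-genome alignment at deletions >= ``min_intron``
    (intron candidates) into exon blocks (qstart, qend, matches, columns)."""
    oriented = read if a.strand == "+" else revcomp(read)
    if a.strand == "+":
        r = a.read_interval[0]
    else:
        r = len(read) - a.read_interval[1]
    q = a.query_interval[0]
    blocks = []
    cur = [q, q, 0, 0]  # qstart, qend, matches, columns
    for num, op in _CIG_RE.findall(a.cigar):
        ln = int(num)
        if op == "M":
            cur[2] += sum(1 for x, y in zip(g[q:q + ln], oriented[r:r + ln])
                          if x == y)
            cur[3] += ln
            q += ln
            r += ln
            cur[1] = q
        elif op == "D":
            if ln >= min_intron:
                blocks.append(cur)
                cur = [q + ln, q + ln, 0, 0]
            else:
                cur[3] += ln
            q += ln
            cur[1] = max(cur[1], q) if ln < min_intron else cur[1]
        elif op == "I":
            cur[3] += ln
            r += ln
    blocks.append(cur)
    return [b for b in blocks if b[1] > b[0]]


def infer_gene_structure(genomic_model: str, cdna: str, min_exon: int = 20,
                         *, k: int = 13, min_identity: float = 80.0,
                         min_intron: int = 30, max_shift: int = 5) -> GeneStructure:
    """Exon/intron structure from a spliced cDNA-to-genome mapping.

    The cDNA is recruited against the genomic model with the alignment
    length threshold lowered to ``min_exon``; alignments are split at
    deletions of >= ``min_intron`` genomic bases (intron candidates), each
    surviving block (length >= ``min_exon``, identity >= ``min_identity``)
    becomes an exon, and each gap between consecutive blocks an intron.
    Junctions are slid (<= ``max_shift`` bp) to prefer GT/AG, then CG/AG,
    before being reported noncanonical.
    """
    g = genomic_model.upper()
    cdna = cdna.upper()
    alignments = _recruit.recruit_reads(
        g, [("cdna", cdna)], k=k, min_read_len=min_exon,
        min_aln_len=min_exon, min_identity=0.0)
    if not alignments:
        raise StructureUndeterminedError("cDNA could not be mapped onto the "
                                         "genomic model")
    strands = {a.strand for a in alignments}
    if len(strands) > 1:
        raise StructureUndeterminedError("cDNA blocks map to both strands")
    blocks = []
    for a in alignments:
        for qs, qe, m, cols in _alignment_blocks(a, g, cdna, min_intron):
            if qe - qs >= min_exon and cols and 100.0 * m / cols >= min_identity:
                blocks.append((qs, qe))
    if not blocks:
        raise StructureUndeterminedError("no cDNA block met the length and "
                                         "identity thresholds")
    # the mapping must explain at least half of the cDNA to be trusted
    if sum(e - s for s, e in blocks) < 0.5 * len(cdna):
        raise StructureUndeterminedError("cDNA blocks cover too little of "
                                         "the cDNA")
    blocks.sort()
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise StructureUndeterminedError("overlapping cDNA blocks")
    exons = [list(b) for b in blocks]
    splices: list[tuple[str, str, str]] = []
    for i in range(len(exons) - 1):
        e, s = exons[i][1], exons[i + 1][0]
        e2, s2 = _slide_junction(g, e, s, max_shift)
        exons[i][1], exons[i + 1][0] = e2, s2
        donor, acceptor = g[e2:e2 + 2], g[s2 - 2:s2]
        splices.append((donor, acceptor, _classify(donor, acceptor)))
    return GeneStructure(exons=[(a, b) for a, b in exons],
                         splice_dinucleotides=splices)


# ---------------------------------------------------------------------------
# Model statistics
# ---------------------------------------------------------------------------

@dataclass
class ModelStats:
    length: int
    n_count: int
    gc_percent: float | None   # N-excluded; None when all-N
    intron_lengths: list[int]
    nonb_fraction: float


def model_stats(model: ConsensusModel | str,
                structure: GeneStructure | None = None) -> ModelStats:
    """Length, N-excluded GC, intron lengths and non-B coverage fraction."""
    seq = model.sequence if isinstance(model, ConsensusModel) else model
    exons = None
    if structure is not None:
        exons = structure.exons
    elif isinstance(model, ConsensusModel):
        exons = model.exons
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])] if exons else []
    gc = gc_percent(seq) if seq else None
    ann = nonb_annotation(seq) if seq else None
    return ModelStats(length=len(seq), n_count=seq.count("N"), gc_percent=gc,
                      intron_lengths=[e - s for s, e in introns],
                      nonb_fraction=ann.fraction if ann else 0.0)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_consensus_fasta(model: ConsensusModel, name: str, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(model.sequence), id=name, description="")],
                str(path), "fasta")


def write_column_tsv(model: ConsensusModel, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "position": np.arange(len(model.sequence)),
        "base": list(model.sequence),
        "depth": model.column_depth,
        "support": np.round(model.support, 4),
    }).to_csv(path, sep="\t", index=False)


def write_structure_gff3(structure: GeneStructure, seqid: str, path,
                         source: str = "nonbcov") -> None:
    """GFF3 output; internal 0-based half-open intervals are converted to
    GFF's 1-based inclusive convention (start+1, end)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if not structure.exons:
            return
        gstart = structure.exons[0][0] + 1
        gend = structure.exons[-1][1]
        fh.write(f"{seqid}\t{source}\tgene\t{gstart}\t{gend}\t.\t+\t.\t"
                 f"ID=gene1\n")
        for i, (s, e) in enumerate(structure.exons, start=1):
            fh.write(f"{seqid}\t{source}\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                     f"ID=exon{i};Parent=gene1\n")
        for i, ((s, e), (d, a, label)) in enumerate(
                zip(structure.introns, structure.splice_dinucleotides), start=1):
            fh.write(f"{seqid}\t{source}\tintron\t{s + 1}\t{e}\t.\t+\t.\t"
                     f"ID=intron{i};Parent=gene1;donor={d};acceptor={a};"
                     f"splice_class={label}\n")
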