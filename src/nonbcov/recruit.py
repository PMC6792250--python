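"""Read recruitment by k-mer seeding and local alignment.

Reads matching a query gene are found via exact k-mer seeds on both
strands, seeds are chained by diagonal, and each candidate locus is
resolved with a local dynamic-programming alignment (match +1,
mismatch -2, gap open -2, gap extend -1 — tolerant of up to ~25% error)
restricted to a seed-defined query window. Per alignment the column
counts (matches, mismatches, insertions, deletions) and percent identity
over all alignment columns are reported.

Thresholds mirror long-read search practice: reads shorter than 400 bp
and alignments shorter than 400 columns or below 70% identity are
discarded by default. Alignments below 75% identity are flagged
low-confidence, the regime where GC-rich long reads stop aligning
reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .seq import revcomp, validate_sequence

__all__ = [
    "ReadAlignment",
    "recruit_reads",
    "alignment_error_rate",
    "is_positive_hit",
    "contamination_fraction",
    "write_alignments_tsv",
    "write_alignments_sam",
]

LOW_CONFIDENCE_IDENTITY = 75.0  # below this, long-read alignments are unreliable


@dataclass
class ReadAlignment:
    """One read-to-query local alignment (forward read coordinates)."""

    read_id: str
    query_interval: tuple[int, int]
    read_interval: tuple[int, int]
    strand: str
    matches: int
    mismatches: int
    insertions: int   # read bases absent from the query
    deletions: int    # query bases absent from the read
    score: float = 0.0
    cigar: str = field(default="", compare=False)

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        """Percent identity over all alignment columns, gaps included."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def low_confidence(self) -> bool:
        return self.identity < LOW_CONFIDENCE_IDENTITY

    def __post_init__(self) -> None:
        qlen = self.query_interval[1] - self.query_interval[0]
        rlen = self.read_interval[1] - self.read_interval[0]
        if qlen != self.matches + self.mismatches + self.deletions:
            raise ValueError("query interval inconsistent with column counts")
        if rlen != self.matches + self.mismatches + self.insertions:
            raise ValueError("read interval inconsistent with column counts")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _kmer_index(query: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        kmer = query[i:i + k]
        if "N" in kmer:  # seeds on literal N never match
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_hits(read: str, index: Mapping[str, list[int]], k: int,
               stride: int = 1, max_occ: int = 50) -> list[tuple[int, int]]:
    """(query_pos, read_pos) exact seed matches; highly repetitive k-mers
    contribute at most ``max_occ`` query positions each."""
    hits = []
    for r in range(0, len(read) - k + 1, stride):
        kmer = read[r:r + k]
        if "N" in kmer:
            continue
        for q in index.get(kmer, ())[:max_occ]:
            hits.append((q, r))
    return hits


def _cluster_seeds(hits: list[tuple[int, int]], read_len: int,
                   band: int, max_clusters: int = 8) -> list[tuple[int, int]]:
    """Candidate query windows from diagonal-clustered seeds.

    Seeds are grouped on the diagonal (query_pos - read_pos) with gaps up
    to ``band``; each cluster's window is the read span projected through
    its median diagonal, padded for indel drift. Windows that largely
    overlap are merged; at most ``max_clusters`` best-supported clusters
    are kept (repetitive queries spawn arbitrarily many equivalent ones).
    """
    if not hits:
        return []
    by_diag = sorted(hits, key=lambda h: (h[0] - h[1], h[0]))
    clusters: list[list[tuple[int, int]]] = []
    for h in by_diag:
        d = h[0] - h[1]
        if clusters:
            last = clusters[-1][-1]
            if d - (last[0] - last[1]) <= band:
                clusters[-1].append(h)
                continue
        clusters.append([h])
    clusters.sort(key=len, reverse=True)
    clusters = clusters[:max_clusters]
    drift = int(0.15 * read_len)
    windows: list[list[int]] = []
    for cl in clusters:
        diags = sorted(q - r for q, r in cl)
        d_med = diags[len(diags) // 2]
        windows.append([d_med - drift, d_med + read_len + drift])
    windows.sort()
    merged: list[list[int]] = []
    for w0, w1 in windows:
        if merged and w0 <= merged[-1][1] - read_len // 2:
            merged[-1][1] = max(merged[-1][1], w1)
        else:
            merged.append([w0, w1])
    return [(a, b) for a, b in merged]


def _count_alignment(alignment, query_w: str, read_s: str):
    """Column counts, intervals and CIGAR from a Bio.Align alignment."""
    tblocks, qblocks = alignment.aligned  # target = query window, query = read
    matches = mismatches = insertions = deletions = 0
    cig: list[str] = []
    prev_t = prev_r = None
    for (ts, te), (rs, re) in zip(tblocks, qblocks):
        if prev_t is not None:
            dt, dr = ts - prev_t, rs - prev_r
            if dt:
                deletions += dt
                cig.append(f"{dt}D")
            if dr:
                insertions += dr
                cig.append(f"{dr}I")
        m = sum(1 for a, b in zip(query_w[ts:te], read_s[rs:re]) if a == b)
        matches += m
        mismatches += (te - ts) - m
        cig.append(f"{te - ts}M")
        prev_t, prev_r = te, re
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    r0, r1 = int(qblocks[0][0]), int(qblocks[-1][1])
    return matches, mismatches, insertions, deletions, (t0, t1), (r0, r1), "".join(cig)


def recruit_reads(query: str, reads, k: int = 13, min_read_len: int = 400,
                  min_aln_len: int = 400, min_identity: float = 70.0,
                  *, seed_stride: int = 1, band: int = 100,
                  window_slack: int = 60) -> list[ReadAlignment]:
    """Recruit reads matching ``query``; one best alignment per read per locus.

    ``reads`` may be a mapping id -> sequence or an iterable of
    (id, sequence) pairs. Candidate loci come from diagonal-clustered exact
    k-mer seeds on both strands; each is aligned locally within a query
    window spanning the cluster plus margins wide enough for the unseeded
    read tails. Alignments shorter than ``min_aln_len`` columns or below
    ``min_identity`` percent are discarded; overlapping survivors at one
    locus are reduced to the best (highest score, then longer alignment,
    then leftmost query start).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    q = validate_sequence(query, "query")
    if len(q) < k:
        raise ValueError("query shorter than the seed size k")
    if isinstance(reads, Mapping):
        read_items = list(reads.items())
    else:
        read_items = [(r[0], r[1]) for r in reads]
    index = _kmer_index(q, k)
    aligner = _make_aligner()
    out: list[ReadAlignment] = []
    for read_id, read_seq in read_items:
        rs = validate_sequence(read_seq, f"read {read_id}")
        if len(rs) < min_read_len:
            continue
        candidates: list[ReadAlignment] = []
        for strand in "+-":
            oriented = rs if strand == "+" else revcomp(rs)
            hits = _seed_hits(oriented, index, k, seed_stride)
            for qs, qe in _cluster_seeds(hits, len(oriented), band):
                w0 = max(0, qs - window_slack)
                w1 = min(len(q), qe + window_slack)
                window = q[w0:w1]
                alns = aligner.align(window, oriented)
                if alns.score <= 0:
                    continue
                aln = alns[0]  # deterministic first optimal path
                (m, x, ins, dele, (t0, t1), (r0, r1), cig) = _count_alignment(
                    aln, window, oriented)
                if strand == "+":
                    read_iv = (r0, r1)
                else:
                    read_iv = (len(rs) - r1, len(rs) - r0)
                candidates.append(ReadAlignment(
                    read_id=read_id,
                    query_interval=(w0 + t0, w0 + t1),
                    read_interval=read_iv, strand=strand,
                    matches=m, mismatches=x, insertions=ins, deletions=dele,
                    score=float(aln.score), cigar=cig))
        kept = [
            a for a in candidates
            if a.columns >= min_aln_len and a.identity >= min_identity
        ]
        out.extend(_best_per_locus(kept))
    out.sort(key=lambda a: (a.query_interval, a.read_id))
    return out


def _best_per_locus(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Reduce alignments of one read to the best per locus.

    Two candidates are the same locus when their query intervals overlap,
    or when they spend the same part of the read (read intervals
    overlapping by more than half of the shorter one — a repetitive query
    offers many placements for one read segment, which must not be
    double-counted). Genuine multi-locus hits use disjoint read segments
    and are all kept.
    """
    ranked = sorted(alignments,
                    key=lambda a: (-a.score, -a.columns, a.query_interval[0]))
    kept: list[ReadAlignment] = []
    for a in ranked:
        s, e = a.query_interval
        rs, re_ = a.read_interval
        same_locus = False
        for k in kept:
            if k.query_interval[0] < e and s < k.query_interval[1]:
                same_locus = True
                break
            ov = min(re_, k.read_interval[1]) - max(rs, k.read_interval[0])
            shorter = min(re_ - rs, k.read_interval[1] - k.read_interval[0])
            if shorter > 0 and ov > 0.5 * shorter:
                same_locus = True
                break
        if not same_locus:
            kept.append(a)
    kept.sort(key=lambda a: a.query_interval)
    return kept


def alignment_error_rate(a: ReadAlignment) -> float:
    """Percent of alignment columns that are errors (100 - identity)."""
    return 100.0 - a.identity


def is_positive_hit(a: ReadAlignment, query_len: int) -> bool:
    """Database positive-hit rule: more than 90% of the query aligned AND
    identity strictly above 95% (both inequalities strict)."""
    aligned_fraction = (a.query_interval[1] - a.query_interval[0]) / query_len
    return aligned_fraction > 0.90 and a.identity > 95.0


def contamination_fraction(n_aligned: int, n_total: int) -> tuple[float, bool]:
    """Percent of aligned reads and the contamination flag.

    Below 2.5% aligned reads counts as no significant contamination; the
    boundary value 2.5% itself is flagged contaminated.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_aligned < 0 or n_aligned > n_total:
        raise ValueError("n_aligned must be within [0, n_total]")
    percent = 100.0 * n_aligned / n_total
    return percent, percent >= 2.5


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_alignments_tsv(alignments: Sequence[ReadAlignment], path) -> None:
    import pandas as pd

    rows = [{
        "read_id": a.read_id,
        "qstart": a.query_interval[0], "qend": a.query_interval[1],
        "rstart": a.read_interval[0], "rend": a.read_interval[1],
        "strand": a.strand, "matches": a.matches, "mismatches": a.mismatches,
        "ins": a.insertions, "del": a.deletions,
        "identity": round(a.identity, 3),
    } for a in alignments]
    pd.DataFrame(rows, columns=["read_id", "qstart", "qend", "rstart", "rend",
                                "strand", "matches", "mismatches", "ins",
                                "del", "identity"]).to_csv(path, sep="\t",
                                                           index=False)


def write_alignments_sam(alignments: Sequence[ReadAlignment],
                         reads: Mapping[str, str], query_id: str,
                         query_len: int, path) -> None:
    """Minimal SAM with CIGAR (soft-clipped read tails, MAPQ 255)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{query_id}\tLN:{query_len}\n")
        for a in sorted(alignments, key=lambda x: x.query_interval):
            seq = reads[a.read_id]
            if a.strand == "-":
                seq = revcomp(seq)
                clip5 = len(seq) - a.read_interval[1]
                clip3 = a.read_interval[0]
            else:
                clip5 = a.read_interval[0]
                clip3 = len(seq) - a.read_interval[1]
            cigar = (f"{clip5}S" if clip5 else "") + a.cigar + \
                    (f"{clip3}S" if clip3 else "")
            flag = 16 if a.strand == "-" else 0
            fh.write(f"{a.read_id}\t{flag}\t{query_id}\t"
                     f"{a.query_interval[0] + 1}\t255\t{cigar}\t*\t0\t0\t"
                     f"{seq}\t*\n")
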