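"""Non-B DNA determinant scanning and GC statistics.

Three classes of non-B determinants are detected on nucleotide sequences:

* **G-quadruplex (G4) motifs** — the strict, degeneracy-free motif of four
  runs of >= 3 guanines separated by loops of 1-12 bases
  (``G3+ N1-12 G3+ N1-12 G3+ N1-12 G3+``), scanned on one or both strands.
* **Tandem repeats** — head-to-tail repetitions of a short unit (exact
  match by default), the sole constituent of the GC-rich introns this
  package models.
* **Dyads (inverted repeats)** — two nearby arms that are reverse
  complements of each other, able to fold into intrastrand hairpins.

All coordinates are 0-based half-open on the forward strand, including for
minus-strand G4 hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seq import merge_intervals, revcomp, validate_sequence

__all__ = [
    "MotifHit",
    "GCTrack",
    "NonBAnnotation",
    "gc_percent",
    "gc_summary",
    "gc_track",
    "scan_g4",
    "scan_tandem",
    "scan_dyad",
    "nonb_annotation",
    "write_motif_bed",
    "summarize_sequences",
]


@dataclass(frozen=True)
class MotifHit:
    """One detected non-B determinant.

    ``detail`` is motif-specific: G-run/loop lengths for g4; unit, period
    and copy count for tandem; arm, loop and mismatch count for dyad.
    """

    kind: str                      # {"g4", "tandem", "dyad"}
    start: int                     # forward-strand coordinates, half-open
    end: int
    strand: str = "+"
    detail: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("g4", "tandem", "dyad"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty motif interval")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GCTrack:
    """Sliding-window GC percentages (window/step in bp)."""

    window: int
    step: int
    values: list[float]


# ---------------------------------------------------------------------------
# GC statistics
# ---------------------------------------------------------------------------

def gc_percent(seq: str) -> float | None:
    """GC content as a percent of unambiguous (non-N) bases.

    Returns ``None`` when the sequence contains no unambiguous base;
    raises ``ValueError`` on an empty sequence.
    """
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def gc_summary(seqs: Sequence[str]) -> tuple[float, float, float]:
    """(median, Q1, Q3) of per-sequence GC percent, linear interpolation."""
    if len(seqs) == 0:
        raise ValueError("gc_summary needs at least one sequence")
    values = [v for v in (gc_percent(s) for s in seqs) if v is not None]
    if not values:
        raise ValueError("no sequence with unambiguous bases")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def gc_track(seq: str, window: int, step: int) -> GCTrack:
    """GC percent in sliding windows; all-N windows yield nan."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    values: list[float] = []
    for start in range(0, len(seq) - window + 1, step):
        v = gc_percent(seq[start:start + window])
        values.append(math.nan if v is None else v)
    return GCTrack(window=window, step=step, values=values)


# ---------------------------------------------------------------------------
# G-quadruplex motifs
# ---------------------------------------------------------------------------

def _g_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= min_run, as (start, end)."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _chain_runs(seq: str, runs: list[tuple[int, int]], first: int,
                n_runs: int, min_loop: int, max_loop: int) -> list[int] | None:
    """Earliest (lexicographic by run start) chain of ``n_runs`` G-runs
    beginning at run index ``first`` with loop lengths in [min_loop, max_loop]
    and loops free of N. Depth-first with backtracking."""

    def extend(idx: int, depth: int, acc: list[int]) -> list[int] | None:
        if depth == n_runs:
            return acc
        end = runs[idx][1]
        for k in range(idx + 1, len(runs)):
            gap = runs[k][0] - end
            if gap > max_loop:
                break
            if gap < min_loop:
                continue
            if "N" in seq[end:runs[k][0]]:
                continue
            out = extend(k, depth + 1, acc + [k])
            if out is not None:
                return out
        return None

    return extend(first, 1, [first])


def scan_g4(seq: str, both_strands: bool = False, *, min_run: int = 3,
            min_loop: int = 1, max_loop: int = 12, n_runs: int = 4) -> list[MotifHit]:
    """Strict G4 motif scan: leftmost, non-overlapping, greedy G-runs.

    G-runs are always taken maximally (a run longer than ``min_run`` is
    absorbed whole, never split); loops may contain any of {A,C,G,T} but a
    literal N breaks both runs and loops. When ``both_strands`` is set the
    reverse complement is scanned identically and hits are mapped back to
    forward coordinates with strand "-". Hits are sorted by start.
    """
    s = validate_sequence(seq)
    hits = [
        MotifHit("g4", a, b, "+", d)
        for a, b, d in _scan_g4_one(s, min_run, min_loop, max_loop, n_runs)
    ]
    if both_strands:
        n = len(s)
        rc = revcomp(s)
        for a, b, d in _scan_g4_one(rc, min_run, min_loop, max_loop, n_runs):
            hits.append(MotifHit("g4", n - b, n - a, "-", d))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _scan_g4_one(seq: str, min_run: int, min_loop: int, max_loop: int,
                 n_runs: int) -> list[tuple[int, int, dict]]:
    runs = _g_runs(seq, min_run)
    out: list[tuple[int, int, dict]] = []
    floor = 0
    j = 0
    while j < len(runs):
        if runs[j][0] < floor:
            j += 1
            continue
        chain = _chain_runs(seq, runs, j, n_runs, min_loop, max_loop)
        if chain is None:
            j += 1
            continue
        start = runs[chain[0]][0]
        end = runs[chain[-1]][1]
        detail = {
            "g_runs": [runs[c][1] - runs[c][0] for c in chain],
            "loops": [runs[b][0] - runs[a][1] for a, b in zip(chain, chain[1:])],
        }
        out.append((start, end, detail))
        floor = end
        j += 1
    return out


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def scan_tandem(seq: str, max_period: int = 20, min_copies: int = 3,
                min_len: int = 12, *, max_mismatch_frac: float = 0.0) -> list[MotifHit]:
    """Exact tandem repeat finder over periods 1..max_period.

    For each period ``p`` the maximal runs where ``seq[i] == seq[i-p]``
    holds contiguously are reported as repeat regions, provided the region
    holds >= ``min_copies`` full copies and spans >= ``min_len`` bases.
    A region already described by a smaller period (nested report) is
    suppressed. ``max_mismatch_frac`` > 0 enables an approximate mode in
    which up to that fraction of positions within a run may violate the
    periodicity (isolated mismatches only, never at run ends).
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    s = validate_sequence(seq)
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    hits: list[MotifHit] = []
    for p in range(1, min(max_period, n - 1) + 1):
        eq = arr[p:] == arr[:-p]
        if max_mismatch_frac > 0.0:
            regions = _approx_runs(eq, p, max_mismatch_frac)
        else:
            regions = _exact_runs(eq)
        for i0, i1 in regions:  # indices into eq; region on seq = [i0, i1 + p)
            start, end = i0, i1 + p
            length = end - start
            copies = length // p
            if copies >= min_copies and length >= min_len:
                unit = s[start:start + p]
                if "N" in s[start:end]:
                    continue
                hits.append(MotifHit("tandem", start, end, "+", {
                    "unit": unit, "period": p, "copies": copies,
                }))
    # suppress nested reports: keep the smallest period describing a run
    hits.sort(key=lambda h: (h.detail["period"], h.start))
    kept: list[MotifHit] = []
    for h in hits:
        if any(k.start <= h.start and h.end <= k.end for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.start, h.detail["period"]))
    return kept


def _exact_runs(eq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in eq, as (start, end) half-open indices."""
    if eq.size == 0:
        return []
    padded = np.concatenate([[False], eq, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _approx_runs(eq: np.ndarray, period: int, frac: float) -> list[tuple[int, int]]:
    """Greedy merge of exact runs across mismatch gaps, keeping the total
    mismatch fraction of each merged region within ``frac``."""
    merged: list[list[int]] = []  # [start, end, n_mismatch]
    for s0, e0 in _exact_runs(eq):
        if merged:
            ps, pe, pm = merged[-1]
            gap = s0 - pe
            if 0 < gap and (pm + gap) / (e0 - ps + period) <= frac:
                merged[-1][1] = e0
                merged[-1][2] = pm + gap
                continue
        merged.append([s0, e0, 0])
    return [(s, e) for s, e, _ in merged]


# ---------------------------------------------------------------------------
# Dyads (inverted repeats)
# ---------------------------------------------------------------------------

try:  # the arm-extension loop is hot; numba is optional but much faster
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit
def _dyad_candidates_core(code, comp, out, min_arm, min_loop, max_loop, max_mm):  # pragma: no cover
    """Enumerate maximal-arm dyad candidates for every loop placement.

    Fills ``out`` (shape (k, 4): start, arm, loop, mismatches) and returns
    the number of rows written. For a loop occupying [c1, c2), arms grow
    outward; the arm is the largest extent whose pair mismatches stay
    within ``max_mm`` and whose outermost pair matches (trailing mismatches
    are trimmed).
    """
    n = code.size
    k = 0
    for c1 in range(1, n):
        lo_max = max_loop if c1 + max_loop <= n else n - c1
        for loop in range(min_loop, lo_max + 1):
            c2 = c1 + loop
            amax = min(c1, n - c2)
            if amax < min_arm:
                continue
            arm = 0
            mism = 0
            best_arm = 0
            best_mm = 0
            while arm < amax:
                left = code[c1 - 1 - arm]
                right = comp[c2 + arm]
                if left == right and left != 78:  # 78 = 'N': never pairs
                    arm += 1
                    best_arm = arm
                    best_mm = mism
                else:
                    if arm == 0:  # a mismatch next to the loop is loop, not arm
                        break
                    mism += 1
                    if mism > max_mm:
                        break
                    arm += 1
            if best_arm >= min_arm:
                out[k, 0] = c1 - best_arm
                out[k, 1] = best_arm
                out[k, 2] = loop
                out[k, 3] = best_mm
                k += 1
    return k


def scan_dyad(seq: str, min_arm: int = 6, max_loop: int = 50,
              max_arm_mismatch: int = 1, *, min_loop: int = 0) -> list[MotifHit]:
    """Inverted-repeat (dyad) candidates able to form intrastrand hairpins.

    For every loop placement, arms grow outward from the loop as long as
    left-arm base i pairs (reverse-complement, Hamming only, no gaps) with
    right-arm base i, tolerating up to ``max_arm_mismatch`` strictly
    internal mismatches; arms never start or end on a mismatch (a mismatch
    adjacent to the loop belongs to the loop) and N never pairs. Candidates
    with arm >= ``min_arm`` are then reduced to local maxima: sorted by
    longer arm, then smaller loop, then leftmost start, and accepted
    greedily when not overlapping an already-accepted hit.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    s = validate_sequence(seq)
    code = np.frombuffer(s.encode(), dtype=np.uint8)
    comp = np.frombuffer(revcomp(s)[::-1].encode(), dtype=np.uint8)  # complement, same order
    out = np.empty((max(1, len(s)) * (max_loop - min_loop + 1), 4), dtype=np.int64)
    k = _dyad_candidates_core(code, comp, out,
                              min_arm, min_loop, max_loop, max_arm_mismatch)
    cand = out[:k]
    order = sorted(range(k), key=lambda i: (-cand[i, 1], cand[i, 2], cand[i, 0]))
    kept: list[MotifHit] = []
    for i in order:
        st, a, l, mm = (int(v) for v in cand[i])
        en = st + 2 * a + l
        if any(kh.start < en and st < kh.end for kh in kept):
            continue
        kept.append(MotifHit("dyad", st, en, "+", {
            "arm": a, "loop": l, "mismatches": mm,
        }))
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# Combined annotation
# ---------------------------------------------------------------------------

@dataclass
class NonBAnnotation:
    """Merged non-B track for one sequence."""

    hits: list[MotifHit]
    intervals: list[tuple[int, int]]   # merged union of all hit intervals
    fraction: float                    # covered bases / sequence length

    def hits_of(self, kind: str) -> list[MotifHit]:
        return [h for h in self.hits if h.kind == kind]


def nonb_annotation(seq: str, *, g4_kwargs: dict | None = None,
                    tandem_kwargs: dict | None = None,
                    dyad_kwargs: dict | None = None) -> NonBAnnotation:
    """Scan all three determinant classes and merge their intervals."""
    s = validate_sequence(seq)
    hits: list[MotifHit] = []
    hits += scan_g4(s, both_strands=True, **(g4_kwargs or {}))
    hits += scan_tandem(s, **(tandem_kwargs or {}))
    hits += scan_dyad(s, **(dyad_kwargs or {}))
    merged = merge_intervals([h.interval for h in hits])
    covered = sum(e - b for b, e in merged)
    fraction = covered / len(s) if s else 0.0
    return NonBAnnotation(hits=sorted(hits, key=lambda h: (h.start, h.kind)),
                          intervals=merged, fraction=fraction)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def motif_bed_lines(hits: Iterable[MotifHit], chrom: str) -> list[str]:
    """BED6 lines: name = kind:detail summary, score = motif-specific length."""
    lines = []
    for h in sorted(hits, key=lambda x: (x.start, x.kind)):
        if h.kind == "g4":
            name = "g4:runs=" + ",".join(map(str, h.detail["g_runs"]))
            score = len(h)
        elif h.kind == "tandem":
            name = f"tandem:{h.detail['unit']}x{h.detail['copies']}"
            score = h.detail["period"] * h.detail["copies"]
        else:
            name = f"dyad:arm={h.detail['arm']},loop={h.detail['loop']}"
            score = h.detail["arm"]
        lines.append(f"{chrom}\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}\n")
    return lines


def write_motif_bed(hits: Iterable[MotifHit], chrom: str, path) -> None:
    with open(path, "w") as fh:
        fh.writelines(motif_bed_lines(hits, chrom))


def summarize_sequences(records: Iterable[tuple[str, str]], **scan_kwargs):
    """Per-sequence annotation summary as a pandas DataFrame.

    Columns: id, length, gc_percent, n_g4_plus, n_g4_minus, tandem_fraction,
    dyad_count, nonb_fraction.
    """
    import pandas as pd

    rows = []
    for name, seq in records:
        ann = nonb_annotation(seq, **scan_kwargs)
        g4 = ann.hits_of("g4")
        tandem_cov = sum(e - b for b, e in
                         merge_intervals([h.interval for h in ann.hits_of("tandem")]))
        rows.append({
            "id": name,
            "length": len(seq),
            "gc_percent": gc_percent(seq),
            "n_g4_plus": sum(1 for h in g4 if h.strand == "+"),
            "n_g4_minus": sum(1 for h in g4 if h.strand == "-"),
            "tandem_fraction": tandem_cov / len(seq) if seq else 0.0,
            "dyad_count": len(ann.hits_of("dyad")),
            "nonb_fraction": ann.fraction,
        })
    return pd.DataFrame(rows)
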