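"""Expected-vs-observed coverage, depletion ratios, depth and patchiness.

The central bookkeeping of the analysis: for a query of length L present
``copy_number`` times in a genome sequenced at ``dataset_depth`` fold, the
expected number of aligned read bases is ``L x copy_number x depth``; the
observed total over recruited alignments divided by that expectation is
the depletion percent (e.g. ~5% and ~11% for GC-rich test genes, versus
~100% for ordinary sequence). Patchiness is the percent of query positions
with zero alignment depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .recruit import ReadAlignment, alignment_error_rate
from .seq import merge_intervals, overlap_length

__all__ = [
    "CoverageReport",
    "expected_coverage_bp",
    "depletion_percent",
    "depth_profile",
    "coverage_report",
    "observed_bp_in_intervals",
    "depletion_over_intervals",
    "write_bedgraph",
]


@dataclass
class CoverageReport:
    """Coverage accounting for one query against one read set."""

    query_id: str
    query_len: int
    copy_number: int
    dataset_depth: float
    observed_bp: int
    expected_bp: float
    depletion_percent: float           # 100 * observed / expected
    depth: np.ndarray = field(repr=False)
    patchiness: float                  # % positions with zero depth
    n_alignments: int
    error_rate_mean: float | None
    error_rate_min: float | None
    error_rate_max: float | None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "depth"}
        d["depletion_percent"] = float(self.depletion_percent)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame([self.to_dict()]).to_csv(path, sep="\t", index=False)


def expected_coverage_bp(query_len: int, copy_number: int,
                         dataset_depth: float) -> float:
    """Expected aligned bases: query_len x copy_number x dataset_depth.

    E.g. a single-copy 14,705 bp query in a 60X dataset is expected to
    accumulate 882,300 aligned bases.
    """
    if query_len <= 0 or copy_number <= 0 or dataset_depth <= 0:
        raise ValueError("query_len, copy_number and dataset_depth must be positive")
    return query_len * copy_number * dataset_depth


def depletion_percent(observed_bp: float, expected_bp: float) -> float:
    """Observed over expected aligned bases, as a percent (full precision)."""
    if expected_bp <= 0:
        raise ValueError("expected_bp must be positive")
    if observed_bp < 0:
        raise ValueError("observed_bp must be non-negative")
    return 100.0 * observed_bp / expected_bp


def depth_profile(alignments: list[ReadAlignment],
                  query_len: int) -> tuple[np.ndarray, float]:
    """Per-position alignment depth and patchiness (% zero-depth positions)."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    delta = np.zeros(query_len + 1, dtype=np.int64)
    for a in alignments:
        s, e = a.query_interval
        if not (0 <= s < e <= query_len):
            raise ValueError(f"alignment interval {a.query_interval} outside "
                             f"[0, {query_len})")
        delta[s] += 1
        delta[e] -= 1
    depth = np.cumsum(delta[:-1])
    patchiness = 100.0 * int((depth == 0).sum()) / query_len
    return depth, patchiness


def coverage_report(query_id: str, query_len: int,
                    alignments: list[ReadAlignment], copy_number: int = 1,
                    dataset_depth: float = 60.0) -> CoverageReport:
    """Assemble the full coverage report for one query."""
    expected = expected_coverage_bp(query_len, copy_number, dataset_depth)
    observed = sum(a.query_interval[1] - a.query_interval[0] for a in alignments)
    depth, patchiness = depth_profile(alignments, query_len)
    errors = [alignment_error_rate(a) for a in alignments]
    return CoverageReport(
        query_id=query_id, query_len=query_len, copy_number=copy_number,
        dataset_depth=dataset_depth, observed_bp=observed, expected_bp=expected,
        depletion_percent=depletion_percent(observed, expected),
        depth=depth, patchiness=patchiness, n_alignments=len(alignments),
        error_rate_mean=float(np.mean(errors)) if errors else None,
        error_rate_min=float(np.min(errors)) if errors else None,
        error_rate_max=float(np.max(errors)) if errors else None)


def observed_bp_in_intervals(alignments: list[ReadAlignment],
                             intervals: list[tuple[int, int]]) -> int:
    """Aligned query bases falling inside the union of ``intervals``."""
    track = merge_intervals(intervals)
    return sum(overlap_length(a.query_interval, t)
               for a in alignments for t in track)


def depletion_over_intervals(alignments: list[ReadAlignment],
                             intervals: list[tuple[int, int]],
                             dataset_depth: float) -> float:
    """Depletion percent restricted to a sub-track of the query (e.g. the
    non-B truth intervals of a synthetic gene)."""
    track = merge_intervals(intervals)
    length = sum(e - s for s, e in track)
    if length == 0:
        raise ValueError("empty interval track")
    observed = observed_bp_in_intervals(alignments, track)
    return depletion_percent(observed, length * dataset_depth)


def write_bedgraph(depth: np.ndarray, chrom: str, path) -> None:
    """Depth profile as bedGraph (0-based half-open, runs collapsed)."""
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [depth.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")
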