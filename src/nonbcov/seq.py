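"""Small sequence and interval utilities shared across the package.

Coordinates are 0-based, half-open throughout; strands are "+" / "-".
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase ``seq`` and check it is over {A,C,G,T,N}."""
    s = seq.upper()
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise ValueError(f"{name} contains non-nucleotide characters: {bad}")
    return s


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence of ``length`` with an exact G+C base count.

    The number of G/C bases is round(length * gc / 100); which strong/weak
    base fills each slot and the slot order are drawn from ``rng``, so the
    realised GC fraction deviates from the target by at most half a base.
    """
    if not 0.0 <= gc <= 100.0:
        raise ValueError(f"GC percent must be in [0, 100], got {gc}")
    if length < 0:
        raise ValueError("length must be non-negative")
    n_gc = int(round(length * gc / 100.0))
    strong = rng.choice(np.array(["G", "C"]), size=n_gc)
    weak = rng.choice(np.array(["A", "T"]), size=length - n_gc)
    arr = np.concatenate([strong, weak])
    rng.shuffle(arr)
    return "".join(arr)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(i[:2] for i in intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intervals_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_fraction(interval: tuple[int, int], track: list[tuple[int, int]]) -> float:
    """Fraction of ``interval`` covered by the union of ``track``."""
    s, e = interval
    if e <= s:
        return 0.0
    covered = sum(overlap_length(interval, t) for t in merge_intervals(track))
    return covered / (e - s)
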