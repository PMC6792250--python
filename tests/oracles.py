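"""Independent brute-force reference implementations used only by tests.

Each function re-derives the result from the operation's definition by
exhaustive enumeration, deliberately avoiding the package's code paths.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# G4: enumerate every chain of four maximal G-runs with 1-12 nt loops,
# then apply the leftmost non-overlapping selection.
# ---------------------------------------------------------------------------

def _maximal_g_runs(seq: str, min_run: int = 3):
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def brute_g4(seq: str, min_loop: int = 1, max_loop: int = 12):
    """All leftmost non-overlapping strict G4 matches on the + strand as
    (start, end, run_lengths, loop_lengths) tuples."""
    runs = _maximal_g_runs(seq)
    matches = []
    nr = len(runs)
    for a in range(nr):
        for b in range(a + 1, nr):
            gap1 = runs[b][0] - runs[a][1]
            if gap1 > max_loop:
                break
            if gap1 < min_loop or "N" in seq[runs[a][1]:runs[b][0]]:
                continue
            for c in range(b + 1, nr):
                gap2 = runs[c][0] - runs[b][1]
                if gap2 > max_loop:
                    break
                if gap2 < min_loop or "N" in seq[runs[b][1]:runs[c][0]]:
                    continue
                for d in range(c + 1, nr):
                    gap3 = runs[d][0] - runs[c][1]
                    if gap3 > max_loop:
                        break
                    if gap3 < min_loop or "N" in seq[runs[c][1]:runs[d][0]]:
                        continue
                    matches.append((a, b, c, d))
    # leftmost, non-overlapping; ties by earliest subsequent runs
    matches.sort(key=lambda m: (runs[m[0]][0], runs[m[1]][0],
                                runs[m[2]][0], runs[m[3]][0]))
    chosen = []
    floor = 0
    for m in matches:
        start, end = runs[m[0]][0], runs[m[3]][1]
        if start < floor:
            continue
        chosen.append((start, end,
                       tuple(runs[i][1] - runs[i][0] for i in m),
                       (runs[m[1]][0] - runs[m[0]][1],
                        runs[m[2]][0] - runs[m[1]][1],
                        runs[m[3]][0] - runs[m[2]][1])))
        floor = end
    return chosen


# ---------------------------------------------------------------------------
# Tandem repeats: per (start, period) maximal extension by direct character
# comparison, then left-maximality, thresholds and nested suppression.
# ---------------------------------------------------------------------------

def brute_tandem(seq: str, max_period: int = 20, min_copies: int = 3,
                 min_len: int = 12):
    """All exact tandem hits as (start, end, period, copies) tuples."""
    n = len(seq)
    raw = []
    for p in range(1, min(max_period, n - 1) + 1):
        for s in range(0, n - p):
            # left-maximal: position s-1 must not extend the run
            if s > 0 and s - 1 + p < n and seq[s - 1] == seq[s - 1 + p]:
                continue
            e = s + p
            while e < n and seq[e] == seq[e - p]:
                e += 1
            if e == s + p:
                continue  # no repetition at all for this (s, p)
            length = e - s
            copies = length // p
            if copies >= min_copies and length >= min_len and "N" not in seq[s:e]:
                raw.append((s, e, p, copies))
    raw = sorted(set(raw), key=lambda h: (h[2], h[0]))
    kept = []
    for s, e, p, c in raw:
        if any(ks <= s and e <= ke for ks, ke, kp, kc in kept):
            continue
        kept.append((s, e, p, c))
    return sorted(kept)


# ---------------------------------------------------------------------------
# Dyads: for every loop placement walk the pair list from the definition,
# then the local-maxima selection re-done from scratch.
# ---------------------------------------------------------------------------

def brute_dyad(seq: str, min_arm: int = 6, max_loop: int = 50,
               max_arm_mismatch: int = 1, min_loop: int = 0):
    """Selected dyad hits as (start, end, arm, loop, mismatches) tuples."""
    n = len(seq)
    candidates = []
    for c1 in range(1, n):
        for loop in range(min_loop, min(max_loop, n - c1) + 1):
            c2 = c1 + loop
            amax = min(c1, n - c2)
            pair_ok = []
            for a in range(amax):
                left, right = seq[c1 - 1 - a], seq[c2 + a]
                pair_ok.append(left != "N" and right != "N"
                               and _COMP[right] == left)
            # arm = largest extent with <= budget internal mismatches whose
            # first and last pairs both match
            if not pair_ok or not pair_ok[0]:
                continue
            best = 0
            mism = 0
            for a in range(amax):
                if pair_ok[a]:
                    best = a + 1
                else:
                    mism += 1
                    if mism > max_arm_mismatch:
                        break
            mm = sum(1 for a in range(best) if not pair_ok[a])
            if best >= min_arm:
                candidates.append((c1 - best, best, loop, mm))
    candidates.sort(key=lambda t: (-t[1], t[2], t[0]))
    chosen = []
    for s, arm, loop, mm in candidates:
        e = s + 2 * arm + loop
        if any(s < ke and ks < e for ks, ke, *_ in chosen):
            continue
        chosen.append((s, e, arm, loop, mm))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Local affine-gap alignment (Gotoh) on full matrices: optimal score.
# Scoring matches the recruiter: match +1, mismatch -2, first gap char -2,
# each further gap char -1.
# ---------------------------------------------------------------------------

def gotoh_local_score(a: str, b: str, match: int = 1, mismatch: int = -2,
                      gap_open: int = -2, gap_extend: int = -1) -> int:
    """Best local alignment score by full dynamic programming."""
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H_prev = [0] * (m + 1)
    E_prev = [NEG] * (m + 1)   # gap in a (consumes b)
    best = 0
    for i in range(1, n + 1):
        H_cur = [0] * (m + 1)
        E_cur = [NEG] * (m + 1)
        F = NEG                # gap in b (consumes a), per row
        ai = a[i - 1]
        for j in range(1, m + 1):
            E_cur[j] = max(H_prev[j] + gap_open, E_prev[j] + gap_extend)
            F = max(H_cur[j - 1] + gap_open, F + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h = max(0, H_prev[j - 1] + s, E_cur[j], F)
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, E_prev = H_cur, E_cur
    return best


# ---------------------------------------------------------------------------
# Quartiles by direct sorting with linear interpolation.
# ---------------------------------------------------------------------------

def quantile_sorted(values, q: float) -> float:
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    pos = q * (len(xs) - 1)
    lo = int(pos)
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac
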