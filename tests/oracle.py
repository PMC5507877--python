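"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the declared semantics alone:
the edit distance is a full (unbanded) dynamic program in numpy and the
reference scanner evaluates it at every position, with no candidate
filtering and no third-party matcher, so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

MIN_SCAN_LEN = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by the full O(len(a)*len(b)) DP."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    idx = np.arange(len(b) + 1)
    prev = idx.copy()
    for i, ca in enumerate(a, 1):
        cost = (bb != ord(ca)).astype(np.int64)
        cur = np.empty_like(prev)
        cur[0] = i
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        # resolve the left-neighbour (insertion) dependency in one pass:
        # cur[j] = min_{i<=j} cur[i] + (j - i)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def oracle_scan(seq: str, adapter: str, max_edits: int = 4,
                window_len: Optional[int] = None
                ) -> List[Tuple[int, int, str, int]]:
    """Reference greedy adapter scan; returns (start, end, orientation, dist).

    Implements the declared semantics directly: full-window global edit
    distance at every position, greedy leftmost acceptance with
    minimum-distance refinement over the next ``max_edits`` positions,
    forward preferred on ties, scaled-threshold prefix matching for
    right-terminal short windows (>= 10 bases).
    """
    L = len(seq)
    w = window_len if window_len is not None else len(adapter)
    k = max_edits
    if L < MIN_SCAN_LEN:
        return []
    a_fw = adapter
    a_rc = revcomp(adapter)

    def dist_at(p: int) -> Optional[Tuple[int, str]]:
        window = seq[p : p + w]
        d_fw = levenshtein(window, a_fw)
        d_rc = levenshtein(window, a_rc)
        d, orientation = (d_fw, "forward") if d_fw <= d_rc else (d_rc, "revcomp")
        return (d, orientation) if d <= k else None

    hits: List[Tuple[int, int, str, int]] = []
    p = 0
    while p <= L - w:
        best = dist_at(p)
        if best is not None:
            best_p = p
            for q in range(p + 1, min(p + k, L - w) + 1):
                if best[0] == 0:
                    break
                cand = dist_at(q)
                if cand is not None and cand[0] < best[0]:
                    best, best_p = cand, q
            hits.append((best_p, best_p + w, best[1], best[0]))
            p = best_p + w
            continue
        p += 1
    def terminal_at(p: int) -> Optional[Tuple[int, str]]:
        m = L - p
        t = math.ceil(k * m / w)
        d_fw = levenshtein(seq[p:], a_fw[:m])
        d_rc = levenshtein(seq[p:], a_rc[:m])
        d, orientation = (d_fw, "forward") if d_fw <= d_rc else (d_rc, "revcomp")
        return (d, orientation) if d <= t else None

    while max(0, L - w + 1) <= p <= L - MIN_SCAN_LEN:
        best = terminal_at(p)
        if best is not None:
            best_p = p
            for q in range(p + 1, min(p + k, L - MIN_SCAN_LEN) + 1):
                if best[0] == 0:
                    break
                cand = terminal_at(q)
                if cand is not None and cand[0] < best[0]:
                    best, best_p = cand, q
            hits.append((best_p, L, best[1], best[0]))
            break
        p += 1
    return hits


def mutate(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_edits`` random edits (sub/ins/del) to a sequence."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(s))) if s else 0
        if op == 0 and s:  # substitution to a different base
            old = s[pos]
            choices = [b for b in "ACGT" if b != old]
            s[pos] = choices[int(rng.integers(0, 3))]
        elif op == 1:  # insertion
            s.insert(pos, "ACGT"[int(rng.integers(0, 4))])
        elif s:  # deletion
            del s[pos]
    return "".join(s)


def mutate_to_distance(seq: str, target: int, rng: np.random.Generator,
                       max_tries: int = 200) -> str:
    """A mutated copy whose edit distance to ``seq`` is exactly ``target``."""
    for _ in range(max_tries):
        cand = mutate(seq, target, rng)
        if levenshtein(cand, seq) == target:
            return cand
    raise RuntimeError(f"could not reach edit distance {target}")
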