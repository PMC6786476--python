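"""Independent brute-force oracles used by the test suite.

These re-derive expected results by direct definition-chasing (plain
Python loops, exhaustive search), deliberately sharing no algorithmic
machinery with the implementations they check.
"""

from __future__ import annotations

from collections import deque

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _comp(s: str) -> str:
    return "".join(_COMP[c] for c in s)


def _revcomp(s: str) -> str:
    return _comp(s)[::-1]


# ---------------------------------------------------------------------
# dispersed maximal repeats: per-shift scan by literal definition
# ---------------------------------------------------------------------

def _oracle_runs(S: str, T2: str, shift: int, k: int, min_len: int):
    """Maximal <=k-mismatch runs of S[x] vs T[(x+shift) % n], circular.

    ``T2`` is the doubled transform so no modulo indexing is needed.
    """
    n = len(S)
    row = T2[shift:shift + n]
    mm = [x for x in range(n)
          if S[x] != row[x] or S[x] == "N" or row[x] == "N"]
    if len(mm) <= k:
        return [(0, n, len(mm))] if n >= min_len else []
    runs = set()
    m = len(mm)
    ext = mm + [p + n for p in mm[:k + 1]]
    for t in range(m):
        length = ext[t + k + 1] - mm[t] - 1
        if length >= min_len:
            runs.add(((mm[t] + 1) % n, length % n if length >= n else length,
                      k))
    return sorted(runs)


def _overlap_circ(a, b, n):
    (sa, la), (sb, lb) = a, b
    best = 0
    for off in (-n, 0, n):
        lo = max(sa, sb + off)
        hi = min(sa + la, sb + off + lb)
        best = max(best, hi - lo)
    return min(best, la, lb)


def oracle_maximal_repeats(seq: str, min_len: int, k: int,
                           classes=("forward", "reverse", "complement",
                                    "inverted")):
    """All maximal repeat pairs as {(class, (a,l), (b,l), mismatches)}."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for cls in classes:
        if cls == "forward":
            T = seq
        elif cls == "complement":
            T = _comp(seq)
        elif cls == "reverse":
            T = seq[::-1]
        else:
            T = _revcomp(seq)
        T2 = T + T
        for shift in range(n):
            if cls == "forward" and shift == 0:
                continue
            for start, length, nm in _oracle_runs(seq, T2, shift, k, min_len):
                if cls in ("forward", "complement"):
                    b = (start + shift) % n
                else:
                    b = (n - shift - start - length) % n
                a = start
                if a == b:
                    continue
                if 2 * _overlap_circ((a, length), (b, length), n) > length:
                    continue
                pa, pb = sorted(((a, length), (b, length)))
                out.add((cls, pa, pb, nm))
    return out


# ---------------------------------------------------------------------
# perfect tandem repeats: all (start, unit) brute force
# ---------------------------------------------------------------------

def oracle_tandem_repeats(seq: str, min_total: int = 10,
                          unit_range=(2, 50)):
    """All maximal primitive perfect tandem arrays on the circle."""
    seq = seq.upper()
    n = len(seq)
    doubled = seq + seq

    def min_period(s):
        for p in range(1, len(s)):
            if all(s[i] == s[i + p] for i in range(len(s) - p)):
                return p
        return len(s)

    out = set()
    for u in range(unit_range[0], min(unit_range[1], n - 1) + 1):
        for start in range(n):
            # grow the longest x-run with S[x] == S[x+u] from `start`
            if seq[(start - 1) % n] == seq[(start - 1 + u) % n]:
                continue  # not left-maximal
            run = 0
            while run < n and doubled[(start + run) % n] == \
                    doubled[(start + run + u) % n]:
                run += 1
            total = min(run + u, n)
            if total < max(min_total, 2 * u):
                continue
            arr = doubled[start:start + total]
            if "N" in arr:
                continue
            if min_period(arr) != u:
                continue
            out.add((start, total, arr[:u]))
        # fully periodic circle
        if all(seq[x] == seq[(x + u) % n] for x in range(n)):
            if n >= max(min_total, 2 * u) and min_period(seq) == u:
                out.add((0, n, seq[:u]))
    return out


# ---------------------------------------------------------------------
# signed reversal distance oracles
# ---------------------------------------------------------------------

def _reversals(perm):
    n = len(perm)
    for i in range(n):
        for j in range(i, n):
            yield (perm[:i] + tuple(-v for v in reversed(perm[i:j + 1]))
                   + perm[j + 1:])


def bfs_distance_table(n: int) -> dict:
    """Exact reversal distance to identity for every signed perm of n."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    q = deque([ident])
    while q:
        p = q.popleft()
        for r in _reversals(p):
            if r not in dist:
                dist[r] = dist[p] + 1
                q.append(r)
    return dist


def _breakpoints(perm) -> int:
    ext = (0,) + perm + (len(perm) + 1,)
    return sum(1 for x, y in zip(ext, ext[1:]) if y != x + 1)


def ida_star_distance(perm) -> int:
    """IDA* with the breakpoint/2 admissible heuristic (independent of
    the cycle-graph machinery)."""
    ident = tuple(range(1, len(perm) + 1))
    if perm == ident:
        return 0

    def h(p):
        return (_breakpoints(p) + 1) // 2

    bound = h(perm)
    while True:
        found = _ida_search(perm, 0, bound, h, ident)
        if found is not None:
            return found
        bound += 1


def _ida_search(p, g, bound, h, ident):
    f = g + h(p)
    if f > bound:
        return None
    if p == ident:
        return g
    for r in _reversals(p):
        res = _ida_search(r, g + 1, bound, h, ident)
        if res is not None:
            return res
    return None
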