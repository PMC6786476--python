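"""Dispersed maximal-repeat and perfect tandem-repeat censuses.

Dispersed repeats come in four orientation classes — forward (direct),
reverse, complement and inverted (reverse complement) — and are maximal
under a Hamming-distance budget: a reported pair cannot be extended in
either direction without exceeding ``max_mismatch`` substitutions.

The scan works on the circular sequence by comparing it against a
transform of itself at every circular offset ("diagonal"); a maximal
k-mismatch run on a diagonal is exactly a maximal repeat pair.  Forward
and complement pairs live on ordinary diagonals (b = a + d), reverse and
inverted pairs on anti-diagonals.  For large minimum lengths an exact
seed join prunes the diagonals first, which makes IR-scale scans cheap.

The e-value is the expected number of chance pairs of the observed
quality: (number of candidate position pairs, 4 n^2) times the binomial
tail P(>= l - k matches in l trials at p = 1/4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

REPEAT_CLASSES = ("forward", "reverse", "complement", "inverted")

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b

_CODE4 = np.full(256, 255, dtype=np.int64)
for _i, _a in enumerate(b"ACGT"):
    _CODE4[_a] = _i

_N = ord("N")


@dataclass(frozen=True)
class RepeatHit:
    cls: str
    start_a: int
    start_b: int
    length: int
    mismatches: int
    e_value: float

    @property
    def interval_a(self) -> tuple[int, int]:
        return (self.start_a, self.start_a + self.length)

    @property
    def interval_b(self) -> tuple[int, int]:
        return (self.start_b, self.start_b + self.length)


@dataclass(frozen=True)
class TandemHit:
    start: int
    total_len: int
    unit: str

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def copies(self) -> float:
        return self.total_len / len(self.unit)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _transform(S: np.ndarray, cls: str) -> np.ndarray:
    if cls == "forward":
        return S
    if cls == "complement":
        return _COMP_TABLE[S]
    if cls == "reverse":
        return S[::-1]
    if cls == "inverted":
        return _COMP_TABLE[S][::-1]
    raise ValueError(f"unknown repeat class {cls!r}")


def repeat_evalue(length: int, mismatches: int, genome_len: int) -> float:
    """Expected chance pairs of >= (length - mismatches) matches."""
    if length < 1:
        raise ValueError("length must be positive")
    tail = stats.binom.sf(length - mismatches - 1, length, 0.25)
    return float(4.0 * genome_len * genome_len * tail)


def _maximal_runs(
    mm: np.ndarray, n: int, k: int, min_len: int
) -> list[tuple[int, int, int]]:
    """Maximal runs with <= k mismatches on a circular 0/1 diagonal.

    ``mm``: sorted mismatch positions.  Returns (start, length, n_mism).
    """
    m = len(mm)
    if m == 0 or m <= k:
        return [(0, n, m)] if n >= min_len else []
    mm = np.asarray(mm, dtype=np.int64)
    right = np.roll(mm, -(k + 1))
    length = (right - mm - 1) % n
    keep = np.flatnonzero(length >= min_len)
    out = {
        (int(mm[t] + 1) % n, int(length[t]), k) for t in keep
    }
    return sorted(out)


def _pair_from_run(
    cls: str, shift: int, start: int, length: int, n: int
) -> tuple[int, int]:
    """Map a diagonal run to the (start_a, start_b) interval pair."""
    if cls in ("forward", "complement"):
        return start, (start + shift) % n
    # anti-diagonal classes: position x matches position (n-1-shift-x) mod n
    b_start = (n - shift - start - length) % n
    return start, b_start


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], n: int) -> int:
    """Overlap length of two circular intervals given as (start, length)."""
    (sa, la), (sb, lb) = a, b
    total = 0
    for off_a in (0, n):
        for off_b in (0, n):
            lo = max(sa + off_a, sb + off_b)
            hi = min(sa + off_a + la, sb + off_b + lb)
            if hi > lo:
                total = max(total, hi - lo)
    return min(total, la, lb)


def _candidate_shifts_seeded(
    S: np.ndarray, T: np.ndarray, cls: str, seed_len: int, n: int
) -> np.ndarray:
    """Diagonals carrying at least one exact seed match (circular)."""
    S2 = np.concatenate([S, S])[: n + seed_len - 1]
    T2 = np.concatenate([T, T])[: n + seed_len - 1]
    c_s, c_t = _CODE4[S2], _CODE4[T2]
    pow4 = 4 ** np.arange(seed_len - 1, -1, -1, dtype=np.int64)

    def codes(c):
        from numpy.lib.stride_tricks import sliding_window_view
        win = sliding_window_view(c, seed_len)[:n]
        bad = (win == 255).any(axis=1)
        vals = win @ pow4
        vals[bad] = -1
        return vals

    cs, ct = codes(c_s), codes(c_t)
    order_s, order_t = np.argsort(cs, kind="stable"), np.argsort(ct, kind="stable")
    ss, tt = cs[order_s], ct[order_t]
    shifts: set[int] = set()
    common = np.intersect1d(ss, tt)
    common = common[common >= 0]
    for v in common:
        xs = order_s[np.searchsorted(ss, v):np.searchsorted(ss, v, "right")]
        ys = order_t[np.searchsorted(tt, v):np.searchsorted(tt, v, "right")]
        d = (ys[None, :] - xs[:, None]).ravel() % n
        shifts.update(int(x) for x in d)
    return np.array(sorted(shifts), dtype=int)


def _scan_class(
    S: np.ndarray,
    cls: str,
    min_len: int,
    k: int,
    shifts: np.ndarray | None = None,
    chunk: int = 256,
) -> list[tuple[int, int, int, int]]:
    """All maximal k-mismatch runs of length >= min_len for one class.

    Returns (shift, start, length, n_mism) tuples.  ``shifts`` restricts
    the diagonals scanned (seeded mode); None scans everything.
    """
    n = len(S)
    T = _transform(S, cls)
    T3 = np.concatenate([T, T, T])
    ncol = n + min_len - 1
    S2 = np.concatenate([S, S])[:ncol]
    # distinct sentinels make N-vs-N a mismatch with a single comparison
    S2 = np.where(S2 == _N, np.uint8(1), S2)
    T3 = np.where(T3 == _N, np.uint8(2), T3)
    if shifts is None:
        if cls in ("forward", "complement"):
            # offsets d and n-d yield the same unordered pairs
            all_shifts = np.arange(1 if cls == "forward" else 0, n // 2 + 1)
        else:
            all_shifts = np.arange(n)
    else:
        all_shifts = np.asarray(shifts, int)
        if cls == "forward":
            all_shifts = all_shifts[all_shifts != 0]
    runs: list[tuple[int, int, int, int]] = []
    for lo in range(0, len(all_shifts), chunk):
        block = all_shifts[lo:lo + chunk]
        if len(block) == 0:
            continue
        contiguous = len(block) == block[-1] - block[0] + 1
        if contiguous:
            from numpy.lib.stride_tricks import as_strided
            base = T3[block[0]:]
            M = as_strided(base, shape=(len(block), ncol), strides=(1, 1))
        else:
            M = np.stack([T3[c:c + ncol] for c in block])
        mism = M != S2[None, :]
        cums = np.zeros((len(block), ncol + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=cums[:, 1:])
        w = cums[:, min_len:] - cums[:, :-min_len]
        cand = np.flatnonzero((w <= k).any(axis=1))
        for ci in cand:
            c = int(block[ci])
            row = S2[:n] != T3[c:c + n]
            mm = np.flatnonzero(row)
            for start, length, nm in _maximal_runs(mm, n, k, min_len):
                runs.append((c, start, length, nm))
    return runs


def find_maximal_repeats(
    sequence: str,
    min_len: int = 20,
    max_mismatch: int = 3,
    max_evalue: float | None = 1e-3,
    classes: tuple[str, ...] = REPEAT_CLASSES,
    circular: bool = True,
    seeded: bool | None = None,
) -> list[RepeatHit]:
    """Enumerate maximal dispersed repeats in the requested classes.

    Each unordered pair is reported once.  Pairs whose intervals overlap
    by more than half the shorter interval are suppressed (tandem arrays
    are the tandem scanner's job), as are trivial self-matches.
    """
    if min_len < 2 * (max_mismatch + 1):
        raise ValueError(
            "min_len must be at least 2*(max_mismatch+1) for seeding"
        )
    bad = set(classes) - set(REPEAT_CLASSES)
    if bad:
        raise ValueError(f"unknown repeat classes: {sorted(bad)}")
    seq = sequence.upper()
    if not circular:
        # pad with N so nothing matches across the artificial junction
        seq = seq + "N" * min_len
    S = _encode(seq)
    n = len(S)
    if n < min_len:
        return []
    if seeded is None:
        seeded = min_len // (max_mismatch + 1) >= 16
    hits: dict[tuple, RepeatHit] = {}
    for cls in classes:
        shifts = None
        if seeded:
            seed_len = min(31, min_len // (max_mismatch + 1))
            T = _transform(S, cls)
            shifts = _candidate_shifts_seeded(S, T, cls, seed_len, n)
        for c, start, length, nm in _scan_class(S, cls, min_len,
                                                max_mismatch, shifts):
            if length > n - (0 if circular else min_len):
                length = n if circular else length
            a, b = _pair_from_run(cls, c, start, length, n)
            if a == b:
                continue  # perfect self-palindrome / identity
            ov = _circ_overlap((a, length), (b, length), n)
            if ov * 2 > length:
                continue
            ev = repeat_evalue(length, nm, n)
            if max_evalue is not None and ev > max_evalue:
                continue
            ka, kb = sorted(((a, length), (b, length)))
            key = (cls, ka, kb)
            if key not in hits:
                hits[key] = RepeatHit(cls, ka[0], kb[0], length, nm, ev)
    return sorted(
        hits.values(), key=lambda h: (-h.length, h.cls, h.start_a, h.start_b)
    )


def find_tandem_repeats(
    sequence: str,
    min_total: int = 10,
    unit_range: tuple[int, int] = (2, 50),
    circular: bool = True,
) -> list[TandemHit]:
    """Perfect tandem arrays with primitive units.

    An array is reported at its smallest unit ("ACACAC" is unit AC, not
    ACAC), must repeat perfectly, span at least ``min_total`` bases and at
    least two full copies, and be maximal (not extendable).
    """
    seq = sequence.upper()
    n_orig = len(seq)
    if not circular:
        seq = seq + "N" * (unit_range[1] + 1)
    S = _encode(seq)
    n = len(S)
    doubled = seq + seq
    out = []
    T2 = np.concatenate([S, S])
    for u in range(unit_range[0], min(unit_range[1], n - 1) + 1):
        shifted = T2[u:u + n]
        mism = (S != shifted) | (S == _N) | (shifted == _N)
        mm = np.flatnonzero(mism)
        if len(mm) == 0:
            # whole circle periodic with period u
            arr = seq
            if len(arr) >= max(min_total, 2 * u) and _min_period(arr) == u:
                out.append(TandemHit(0, n, seq[:u]))
            continue
        for t in range(len(mm)):
            left = int(mm[t])
            right = int(mm[(t + 1) % len(mm)])
            start = (left + 1) % n
            run = (right - left - 1) % n
            total = run + u
            if total > n:
                total = n
            if total < max(min_total, 2 * u):
                continue
            arr = doubled[start:start + total]
            if _min_period(arr) != u:
                continue
            out.append(TandemHit(start, total, arr[:u]))
    if not circular:
        out = [h for h in out
               if h.start < n_orig and h.start + h.total_len <= n_orig]
    uniq = {(h.start, h.total_len, h.unit): h for h in out}
    return sorted(uniq.values(), key=lambda h: (h.start, h.unit_len))


def _min_period(s: str) -> int:
    """Smallest p with s[i] == s[i+p] for all valid i."""
    for p in range(1, len(s)):
        if all(s[i] == s[i + p] for i in range(len(s) - p)):
            return p
    return len(s)


def repeat_density(
    hits: list[RepeatHit], genome_len: int
) -> dict[str, float]:
    """Repeats per kb and the fraction of genomic bases inside repeats."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    count_density = len(hits) * 1000.0 / genome_len
    marks = []
    for h in hits:
        for s, l in ((h.start_a, h.length), (h.start_b, h.length)):
            s %= genome_len
            if s + l <= genome_len:
                marks.append((s, s + l))
            else:
                marks.append((s, genome_len))
                marks.append((0, s + l - genome_len))
    merged_bp = 0
    for s, e in _merge_intervals(marks):
        merged_bp += e - s
    return {
        "count_density_per_kb": count_density,
        "bp_fraction": merged_bp / genome_len,
        "n_hits": len(hits),
        "repeat_bp": merged_bp,
    }


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]
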