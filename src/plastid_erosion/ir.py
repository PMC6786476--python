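"""Large inverted-repeat detection and validation.

Candidates come from inverted self-matches of the assembly (delegating to
the repeat-census diagonal-scan core, seeded with exact 31-mers — cheap
because IR-scale matches guarantee long exact seeds).  A candidate is
accepted when read pairs straddle all four IR/single-copy junctions
(one mate anchored in unique sequence next to a junction, the other
inside the repeat), or — for assemblies in which the IR is collapsed to
one copy — when the repeat interval shows the doubled read depth
expected of a collapsed duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import PairedPlacements
from .repeats import _candidate_shifts_seeded, _encode, _pair_from_run, \
    _scan_class, _transform


@dataclass(frozen=True)
class IRCandidate:
    """A pair of inverted intervals (interval_b None = collapsed copy)."""

    interval_a: tuple[int, int]
    interval_b: tuple[int, int] | None
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.interval_a[1] - self.interval_a[0]


@dataclass
class CoverageProfile:
    depth: np.ndarray

    @property
    def genome_len(self) -> int:
        return len(self.depth)

    def interval_mean(self, interval: tuple[int, int]) -> float:
        n = self.genome_len
        s, e = interval
        idx = np.arange(s, e) % n
        return float(self.depth[idx].mean())


@dataclass
class SplitPairEvidence:
    candidate: IRCandidate
    junction_support: dict[int, int]
    n_split_pairs: int
    anchor_regions: dict[str, int] = field(default_factory=dict)

    @property
    def min_junction_support(self) -> int:
        return min(self.junction_support.values()) if self.junction_support else 0


@dataclass
class IRCall:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int] | None
    length: int
    method: str  # "split_pairs" or "coverage_ratio"
    junction_support: dict[int, int] | None = None
    coverage_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "interval_a": list(self.interval_a),
            "interval_b": list(self.interval_b) if self.interval_b else None,
            "length": self.length,
            "method": self.method,
            "junction_support": {str(k): v for k, v in
                                 (self.junction_support or {}).items()},
            "coverage_ratio": self.coverage_ratio,
        }


def find_inverted_candidates(
    sequence: str,
    min_len: int = 1000,
    max_mismatch: int = 0,
) -> list[IRCandidate]:
    """Maximal inverted self-matches of length >= min_len (circular).

    Large-IR calling only; ``min_len`` below 50 belongs to the repeat
    census, not here.  Sorted by length descending.
    """
    if min_len < 50:
        raise ValueError("min_len < 50: use the repeat census instead")
    S = _encode(sequence.upper())
    n = len(S)
    if n < min_len:
        return []
    seed_len = min(31, max(16, min_len // (max_mismatch + 1) // 4))
    T = _transform(S, "inverted")
    shifts = _candidate_shifts_seeded(S, T, "inverted", seed_len, n)
    seen = {}
    for c, start, length, nm in _scan_class(S, "inverted", min_len,
                                            max_mismatch, shifts):
        a, b = _pair_from_run("inverted", c, start, length, n)
        if a == b:
            continue
        ka, kb = sorted(((a, length), (b, length)))
        # the two copies must not overlap on the circle
        if _circular_intervals_overlap(ka, kb, n):
            continue
        key = (ka, kb)
        if key not in seen:
            seen[key] = IRCandidate(
                (ka[0], ka[0] + length), (kb[0], kb[0] + length), nm
            )
    return sorted(seen.values(), key=lambda x: (-x.length, x.interval_a))


def _circular_intervals_overlap(a, b, n) -> bool:
    (sa, la), (sb, lb) = a, b
    for off in (-n, 0, n):
        if max(sa, sb + off) < min(sa + la, sb + off + lb):
            return True
    return False


def coverage_profile(
    placements: PairedPlacements, genome_len: int | None = None
) -> CoverageProfile:
    """Per-base read depth with circular wrap."""
    n = genome_len or placements.genome_len
    diff = np.zeros(n + 1, dtype=np.int64)
    for pos, lens, mapped in (
        (placements.pos1, placements.len1, placements.mapped1),
        (placements.pos2, placements.len2, placements.mapped2),
    ):
        p = pos[mapped] % n
        l = lens[mapped]
        if (p < 0).any() or (p >= n).any():
            raise ValueError("placement out of range")
        e = p + l
        wrap = e > n
        np.add.at(diff, p, 1)
        np.add.at(diff, np.minimum(e, n), -1)
        if wrap.any():
            diff[0] += int(wrap.sum())
            np.add.at(diff, e[wrap] - n, -1)
    return CoverageProfile(np.cumsum(diff[:-1]))


def _circ_dist_forward(a: int, b: int, n: int) -> int:
    return (b - a) % n


def split_pair_evidence(
    placements: PairedPlacements,
    candidate: IRCandidate,
    insert_slack_sd: float = 4.0,
) -> SplitPairEvidence:
    """Count discordant read pairs split across the IR copies.

    Because the mapper collapses the two identical copies to the
    leftmost, every fragment crossing a junction of the *other* copy
    yields a discordant pair: one mate anchored in unique sequence, the
    other placed in the repeat far away (aberrant implied insert).  In a
    genome without a duplicated repeat all pairs are concordant and the
    count is zero.  Each discordant pair supports one single-copy-side
    junction (via its anchor) and one repeat-side junction (via the
    displaced mate pressing against the copy boundary).
    """
    if len(placements.pos2) != len(placements.pos1):
        raise ValueError("unpaired input")
    n = placements.genome_len
    ivs = [candidate.interval_a]
    if candidate.interval_b is not None:
        ivs.append(candidate.interval_b)
    junctions = []
    for s, e in ivs:
        junctions.extend([s % n, e % n])
    W = int(placements.insert_mean + insert_slack_sd * placements.insert_sd)

    def in_ir(pos: int, length: int) -> bool:
        return any(
            _circ_dist_forward(s % n, pos % n, n) + length <= (e - s)
            for s, e in ivs
        )

    support = {j: 0 for j in junctions}
    n_split = 0
    anchors = {"left_flank": 0, "right_flank": 0}
    both = placements.mapped1 & placements.mapped2
    for i in np.flatnonzero(both):
        mates = [
            (int(placements.pos1[i]), placements.strand1[i],
             int(placements.len1[i])),
            (int(placements.pos2[i]), placements.strand2[i],
             int(placements.len2[i])),
        ]
        flags = [in_ir(p, l) for p, _, l in mates]
        if flags[0] == flags[1]:
            continue
        # concordant pairs (proper orientation, sane implied insert) are
        # explained by a contiguous fragment and carry no IR signal
        (p1, s1, l1), (p2, s2, l2) = mates
        concordant = False
        if s1 != s2:
            plus = mates[0] if s1 == "+" else mates[1]
            minus = mates[1] if s1 == "+" else mates[0]
            frag = _circ_dist_forward(plus[0] % n,
                                      (minus[0] + minus[2]) % n, n)
            concordant = max(l1, l2) <= frag <= W
        if concordant:
            continue
        n_split += 1
        for (mpos, mstrand, mlen), is_ir_side in zip(mates, flags):
            for j in junctions:
                if mstrand == "+":
                    d = _circ_dist_forward((mpos + mlen) % n, j, n)
                else:
                    d = _circ_dist_forward(j, mpos % n, n)
                if d <= W - 2 * mlen:
                    support[j] += 1
                    if not is_ir_side:
                        side = ("left_flank" if mstrand == "+"
                                else "right_flank")
                        anchors[side] += 1
    return SplitPairEvidence(candidate, support, n_split, anchors)


@dataclass
class IRCallConfig:
    min_ir_len: int = 1000
    min_pairs: int = 5
    cov_ratio_window: tuple[float, float] = (1.7, 2.3)


def call_ir(
    candidates: list[IRCandidate],
    coverage: CoverageProfile | None = None,
    split_evidence=None,
    config: IRCallConfig = IRCallConfig(),
) -> IRCall | None:
    """Accept the best-supported IR candidate, or None.

    ``split_evidence`` is a callable mapping a candidate to its
    :class:`SplitPairEvidence` (e.g. a closure over read placements).
    Two-copy candidates are accepted when every junction has at least
    ``min_pairs`` straddling pairs; single-interval candidates (collapsed
    assemblies) when the interval's mean depth over the flanking mean
    falls inside ``cov_ratio_window``.  Boundaries are reported at the
    outermost bases consistent with the self-match and read evidence.
    """
    for cand in sorted(candidates, key=lambda c: -c.length):
        if cand.length < config.min_ir_len:
            continue
        if cand.interval_b is not None and split_evidence is not None:
            ev = split_evidence(cand)
            if (ev.junction_support
                    and all(v >= config.min_pairs
                            for v in ev.junction_support.values())):
                return IRCall(cand.interval_a, cand.interval_b, cand.length,
                              "split_pairs", ev.junction_support)
        if coverage is not None:
            n = coverage.genome_len
            inside = coverage.interval_mean(cand.interval_a)
            s, e = cand.interval_a
            flank_idx = np.concatenate(
                [np.arange(s - cand.length, s), np.arange(e, e + cand.length)]
            ) % n
            flank = float(coverage.depth[flank_idx].mean())
            if flank > 0:
                ratio = inside / flank
                lo, hi = config.cov_ratio_window
                if cand.interval_b is None and lo <= ratio <= hi:
                    return IRCall(cand.interval_a, None, cand.length,
                                  "coverage_ratio", None, ratio)
    return None
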