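"""Collinear blocks, signed permutations, and rearrangement distances.

Plastomes are linearized (IRs collapsed to one copy first, as large
duplications confound whole-genome collinearity), shared single-copy
genes serve as anchors, and maximal runs of anchors that are collinear
and equioriented in every genome become blocks.  Block orders are
encoded as signed permutations; distances are the signed breakpoint
count and the exact signed reversal distance computed from the
breakpoint-graph cycle decomposition with hurdle and fortress
corrections.  Rearrangement counts over a fixed tree come from a
deterministic local-improvement labeling of internal nodes (a heuristic;
flagged as such in the output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .genes import base_name
from .genome import Plastome, QuadripartiteMap

SignedPerm = tuple[int, ...]


# ---------------------------------------------------------------------
# IR collapse
# ---------------------------------------------------------------------

def collapse_ir(plastome: Plastome, qmap: QuadripartiteMap) -> Plastome:
    """Remove the IRb copy (features inside it are dropped)."""
    if not qmap.has_ir:
        return plastome
    n = len(plastome)
    s, e = qmap.irb
    # rotate so IRb does not wrap the origin
    if e > n:
        plastome = plastome.rotated(s % n)
        shift = s % n
        s, e = 0, e - s
        qmap = QuadripartiteMap(
            n,
            ((qmap.lsc[0] - shift) % n, (qmap.lsc[0] - shift) % n + qmap.lsc_len),
            ((qmap.ssc[0] - shift) % n, (qmap.ssc[0] - shift) % n + qmap.ssc_len),
            ((qmap.ira[0] - shift) % n, (qmap.ira[0] - shift) % n + qmap.ir_len),
            (0, qmap.ir_len),
        )
        s, e = qmap.irb
    seq = plastome.sequence[:s] + plastome.sequence[e:]
    feats = []
    for f in plastome.features:
        if s <= f.start and f.end <= e:
            continue  # inside IRb
        if f.start >= e:
            import dataclasses
            f = dataclasses.replace(f, start=f.start - (e - s),
                                    end=f.end - (e - s))
        feats.append(f)
    return Plastome(plastome.id, seq, plastome.circular, feats)


# ---------------------------------------------------------------------
# locally collinear blocks
# ---------------------------------------------------------------------

@dataclass
class LCBSet:
    """Blocks shared by all genomes, with per-genome placement."""

    n_blocks: int
    per_genome: dict[str, list[tuple[int, int, int, str]]]
    # genome id -> ordered (block_id, start, end, strand)
    anchor_gene: str = ""

    def permutations(self) -> dict[str, SignedPerm]:
        """Signed block orders, linearized at the anchor block, +."""
        out = {}
        for gid, blocks in self.per_genome.items():
            perm = tuple(
                b if strand == "+" else -b
                for b, _, _, strand in blocks
            )
            out[gid] = canonical_frame(perm)
        return out


def canonical_frame(perm: SignedPerm, anchor: int = 1) -> SignedPerm:
    """Rotate/reflect a circular signed order so ``anchor`` is first, +."""
    idx = next(i for i, v in enumerate(perm) if abs(v) == anchor)
    rotated = perm[idx:] + perm[:idx]
    if rotated[0] < 0:
        rotated = tuple(-v for v in reversed(rotated))
        rotated = rotated[-1:] + rotated[:-1]
    return rotated


def build_lcbs(
    plastomes: list[Plastome],
    anchor_mode: str = "gene",
    min_block_len: int = 0,
) -> LCBSet:
    """Chain shared single-copy anchors into collinear blocks.

    Genomes are treated as linear in their stored rotation (collapse IRs
    and rotate to a common origin first).  Anchors present exactly once
    in every genome are chained; a junction between reference-adjacent
    anchors survives iff the two anchors are adjacent and equioriented in
    every genome.  Blocks shorter than ``min_block_len`` (in the first
    genome) are discarded and the remaining anchors re-chained.
    """
    if len(plastomes) < 2:
        raise ValueError("need at least two genomes")
    if anchor_mode != "gene":
        raise ValueError("only gene anchors are implemented")

    def anchor_list(p: Plastome):
        counts: dict[str, int] = {}
        for f in p.features:
            counts[base_name(f.name)] = counts.get(base_name(f.name), 0) + 1
        return {
            base_name(f.name): f
            for f in p.features
            if counts[base_name(f.name)] == 1
        }

    per = [anchor_list(p) for p in plastomes]
    shared = set(per[0])
    for d in per[1:]:
        shared &= set(d)
    if not shared:
        raise ValueError("genomes share no single-copy anchors")

    active = set(shared)
    while True:
        ref = plastomes[0]
        ref_anchors = sorted(
            (f.start, name) for name, f in per[0].items() if name in active
        )
        order_ref = [name for _, name in ref_anchors]
        ref_id = {name: i + 1 for i, name in enumerate(order_ref)}
        ref_strand = {name: per[0][name].strand for name in order_ref}

        signed_orders = []
        for d in per:
            seq = sorted((f.start, name) for name, f in d.items()
                         if name in active)
            signed = [
                ref_id[name] if d[name].strand == ref_strand[name]
                else -ref_id[name]
                for _, name in seq
            ]
            signed_orders.append(signed)

        m = len(order_ref)
        conserved = []
        for i in range(1, m):  # junction between ids i and i+1
            ok = True
            for signed in signed_orders:
                pos = {abs(v): j for j, v in enumerate(signed)}
                j1, j2 = pos[i], pos[i + 1]
                v1, v2 = signed[j1], signed[j2]
                adj = (j2 == j1 + 1 and v1 == i and v2 == i + 1) or (
                    j1 == j2 + 1 and v2 == -(i + 1) and v1 == -i
                )
                if not adj:
                    ok = False
                    break
            conserved.append(ok)

        # blocks = runs of ids over conserved junctions
        blocks: list[list[int]] = [[1]]
        for i in range(1, m):
            if conserved[i - 1]:
                blocks[-1].append(i + 1)
            else:
                blocks.append([i + 1])

        # length filter (span in the reference genome)
        drop: set[str] = set()
        if min_block_len > 0:
            for blk in blocks:
                names = [order_ref[i - 1] for i in blk]
                span = (
                    max(per[0][nm].end for nm in names)
                    - min(per[0][nm].start for nm in names)
                )
                if span < min_block_len:
                    drop.update(names)
        if not drop:
            break
        active -= drop
        if not active:
            raise ValueError("all anchors removed by min_block_len")

    id_to_block = {}
    for b, blk in enumerate(blocks, start=1):
        for i in blk:
            id_to_block[i] = (b, blk)

    per_genome: dict[str, list[tuple[int, int, int, str]]] = {}
    for p, d, signed in zip(plastomes, per, signed_orders):
        placed = []
        seen = set()
        seq = sorted((f.start, name) for name, f in d.items() if name in active)
        for _, name in seq:
            b, blk = id_to_block[ref_id[name]]
            if b in seen:
                continue
            seen.add(b)
            names = [order_ref[i - 1] for i in blk]
            start = min(d[nm].start for nm in names)
            end = max(d[nm].end for nm in names)
            first = order_ref[blk[0] - 1]
            strand = "+" if d[first].strand == ref_strand[first] else "-"
            # orientation of the run in this genome
            if len(blk) > 1:
                pos = {abs(v): j for j, v in enumerate(
                    [ref_id[nm2] if d[nm2].strand == ref_strand[nm2]
                     else -ref_id[nm2] for _, nm2 in seq])}
                strand = "+" if pos[blk[0]] < pos[blk[-1]] else "-"
            placed.append((b, start, end, strand))
        per_genome[p.id] = placed
    return LCBSet(len(blocks), per_genome,
                  anchor_gene=order_ref[0] if order_ref else "")


# ---------------------------------------------------------------------
# signed permutation distances
# ---------------------------------------------------------------------

def _relabel(perm_a: SignedPerm, perm_b: SignedPerm) -> SignedPerm:
    """Express a in the frame where b is the identity."""
    if sorted(abs(v) for v in perm_a) != sorted(abs(v) for v in perm_b):
        raise ValueError("permutations are over different block sets")
    inv = {}
    for i, v in enumerate(perm_b, start=1):
        inv[abs(v)] = i if v > 0 else -i
    return tuple(
        inv[abs(v)] if v > 0 else -inv[abs(v)] for v in perm_a
    )


def breakpoint_distance(
    perm_a: SignedPerm, perm_b: SignedPerm, framing: str = "linear"
) -> int:
    """Signed breakpoints of a relative to b.

    Linear framing adds end caps 0 and n+1; circular framing closes the
    order around the circle.
    """
    pi = _relabel(perm_a, perm_b)
    n = len(pi)
    if framing == "linear":
        ext = (0,) + pi + (n + 1,)
        return sum(1 for x, y in zip(ext, ext[1:]) if y != x + 1)
    if framing == "circular":
        count = 0
        for i in range(n):
            x, y = pi[i], pi[(i + 1) % n]
            good = (y == x + 1) or (x == n and y == 1) \
                or (x == -1 and y == -n)
            count += 0 if good else 1
        return count
    raise ValueError(f"unknown framing {framing!r}")


def _breakpoint_graph_cycles(pi: SignedPerm):
    """Cycles of the breakpoint graph of the extended permutation.

    Returns (cycles, positions u, pos_of) where each cycle is a list of
    (black edge, direction) traversals; black edges are position pairs.
    """
    n = len(pi)
    u = [0]
    for v in pi:
        if v > 0:
            u.extend([2 * v - 1, 2 * v])
        else:
            u.extend([-2 * v, -2 * v - 1])
    u.append(2 * n + 1)
    pos_of = {v: i for i, v in enumerate(u)}

    def black_partner(p: int) -> int:
        return p + 1 if p % 2 == 0 else p - 1

    def gray_partner(p: int) -> int:
        v = u[p]
        w = v + 1 if v % 2 == 0 else v - 1
        return pos_of[w]

    visited = [False] * (2 * n + 2)
    cycles = []
    for start in range(2 * n + 2):
        if visited[start]:
            continue
        cyc_black = []  # (min_pos, direction) per black edge
        cyc_gray = []   # (min_pos, max_pos) per gray edge
        points = []
        p = start
        while True:
            visited[p] = True
            q = black_partner(p)
            visited[q] = True
            points.extend([p, q])
            cyc_black.append((min(p, q), +1 if q > p else -1))
            r = gray_partner(q)
            cyc_gray.append((min(q, r), max(q, r)))
            p = r
            if p == start:
                break
        cycles.append({
            "black": cyc_black,
            "gray": cyc_gray,
            "points": sorted(set(points)),
            "oriented": len({d for _, d in cyc_black}) > 1,
            "trivial": len(cyc_black) == 1,
        })
    return cycles


def _gray_edges_cross(e1, e2) -> bool:
    (a, b), (c, d) = e1, e2
    return (a < c < b < d) or (c < a < d < b)


def _hurdles_and_fortress(cycles) -> tuple[int, int]:
    """Count hurdles and detect a fortress from the cycle decomposition."""
    nontrivial = [c for c in cycles if not c["trivial"]]
    if not nontrivial:
        return 0, 0
    # interleaving components via union-find on crossing gray edges
    parent = list(range(len(nontrivial)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(nontrivial)), 2):
        if any(
            _gray_edges_cross(e1, e2)
            for e1 in nontrivial[i]["gray"]
            for e2 in nontrivial[j]["gray"]
        ):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    comps: dict[int, dict] = {}
    for i, c in enumerate(nontrivial):
        r = find(i)
        comp = comps.setdefault(r, {"points": [], "oriented": False})
        comp["points"].extend(c["points"])
        comp["oriented"] = comp["oriented"] or c["oriented"]

    unoriented = [c for c in comps.values() if not c["oriented"]]
    if not unoriented:
        return 0, 0

    def hurdle_set(comp_list) -> list[int]:
        """Indices of components whose points are cyclically contiguous
        within the merged point order of all listed components."""
        labeled = []
        for idx, comp in enumerate(comp_list):
            labeled.extend((p, idx) for p in comp["points"])
        labeled.sort()
        labels = [l for _, l in labeled]
        k = len(labels)
        hurdles = []
        for idx in range(len(comp_list)):
            # count circular blocks of this label
            blocks = 0
            for i in range(k):
                if labels[i] == idx and labels[(i - 1) % k] != idx:
                    blocks += 1
            if blocks <= 1:
                hurdles.append(idx)
        return hurdles

    hurdles = hurdle_set(unoriented)
    h = len(hurdles)
    if h == 0:
        return 0, 0
    # fortress: odd number of hurdles, every hurdle a super hurdle
    if h % 2 == 1 and len(unoriented) > h:
        all_super = True
        for hu in hurdles:
            rest = [c for i, c in enumerate(unoriented) if i != hu]
            before = set(hurdle_set(unoriented)) - {hu}
            after = set(hurdle_set(rest))
            # map indices: rest keeps relative order
            remap = {}
            j = 0
            for i in range(len(unoriented)):
                if i != hu:
                    remap[j] = i
                    j += 1
            after_orig = {remap[i] for i in after}
            if not (after_orig - before):
                all_super = False
                break
        if all_super:
            return h, 1
    return h, 0


def reversal_distance(
    perm_a: SignedPerm, perm_b: SignedPerm | None = None
) -> int:
    """Exact minimum number of signed reversals from a to b (identity)."""
    pi = perm_a if perm_b is None else _relabel(perm_a, perm_b)
    n = len(pi)
    if pi == tuple(range(1, n + 1)):
        return 0
    cycles = _breakpoint_graph_cycles(pi)
    c = len(cycles)
    h, f = _hurdles_and_fortress(cycles)
    return (n + 1) - c + h + f


def reversal_distance_lower_bound(
    perm_a: SignedPerm, perm_b: SignedPerm | None = None
) -> int:
    """Cycle lower bound (n + 1 - c), exact up to hurdles/fortress."""
    pi = perm_a if perm_b is None else _relabel(perm_a, perm_b)
    n = len(pi)
    cycles = _breakpoint_graph_cycles(pi)
    return (n + 1) - len(cycles)


def all_reversals(perm: SignedPerm):
    """All signed permutations one reversal away."""
    n = len(perm)
    out = []
    for i in range(n):
        for j in range(i, n):
            out.append(
                perm[:i]
                + tuple(-v for v in reversed(perm[i:j + 1]))
                + perm[j + 1:]
            )
    return out


# ---------------------------------------------------------------------
# rearrangements over a fixed tree
# ---------------------------------------------------------------------

@dataclass
class TreeRearrangementResult:
    total: int
    per_branch: dict[str, int]
    heuristic: bool = True
    node_labels: dict[str, SignedPerm] = field(default_factory=dict)


def count_tree_rearrangements(
    tree, leaf_permutations: dict[str, SignedPerm], max_rounds: int = 4
) -> TreeRearrangementResult:
    """Total reversal count over a fixed rooted tree (heuristic).

    Internal labels are chosen by Sankoff dynamic programming over a
    finite candidate universe — the observed leaf labels plus their
    one-reversal neighborhoods — which solves the labeling problem
    exactly *within that universe*; the universe is then augmented with
    one-reversal neighbors of the chosen internal labels and the DP
    repeated until the total stops improving.  The result is an upper
    bound on the unconstrained minimum and is flagged heuristic.
    """
    leaves = {t.taxon.label for t in tree.leaf_node_iter()}
    if leaves != set(leaf_permutations):
        raise ValueError("tree labels do not match permutation labels")

    memo: dict[tuple[SignedPerm, SignedPerm], int] = {}

    def dist(a: SignedPerm, b: SignedPerm) -> int:
        if a == b:
            return 0
        key = (a, b) if a <= b else (b, a)
        if key not in memo:
            memo[key] = reversal_distance(key[0], key[1])
        return memo[key]

    leaf_labels = {
        id(node): tuple(leaf_permutations[node.taxon.label])
        for node in tree.leaf_node_iter()
    }
    universe: set[SignedPerm] = set(leaf_labels.values())
    for lab in list(universe):
        universe.update(all_reversals(lab))

    labels: dict[int, SignedPerm] = dict(leaf_labels)
    best_total = None
    for _ in range(max_rounds):
        U = sorted(universe)
        cost: dict[int, dict[SignedPerm, int]] = {}
        choice: dict[int, dict[SignedPerm, dict[int, SignedPerm]]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            cost[id(node)] = {}
            choice[id(node)] = {}
            for u in U:
                total = 0
                picks = {}
                for ch in node.child_nodes():
                    if ch.is_leaf():
                        total += dist(u, leaf_labels[id(ch)])
                    else:
                        w_best = min(
                            cost[id(ch)],
                            key=lambda w: (cost[id(ch)][w] + dist(u, w), w),
                        )
                        total += cost[id(ch)][w_best] + dist(u, w_best)
                        picks[id(ch)] = w_best
                cost[id(node)][u] = total
                choice[id(node)][u] = picks
        root = tree.seed_node
        u_root = min(cost[id(root)], key=lambda u: (cost[id(root)][u], u))
        total = cost[id(root)][u_root]
        # backtrack
        stack = [(root, u_root)]
        while stack:
            node, u = stack.pop()
            labels[id(node)] = u
            for ch in node.child_nodes():
                if not ch.is_leaf():
                    stack.append((ch, choice[id(node)][u][id(ch)]))
        if best_total is not None and total >= best_total:
            break
        best_total = total
        before = len(universe)
        for node in tree.preorder_internal_node_iter():
            universe.update(all_reversals(labels[id(node)]))
        if len(universe) == before:
            break

    total = 0
    per_branch: dict[str, int] = {}
    node_labels: dict[str, SignedPerm] = {}
    for node in tree.preorder_node_iter():
        name = (
            node.taxon.label if node.is_leaf()
            else (node.label or f"node{id(node) % 10000}")
        )
        node_labels[name] = labels[id(node)]
        if node.parent_node is not None:
            d = dist(labels[id(node)], labels[id(node.parent_node)])
            per_branch[name] = d
            total += d
    return TreeRearrangementResult(total, per_branch, True, node_labels)
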