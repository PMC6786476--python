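"""Collinear blocks, permutation distances, tree rearrangements."""

import dataclasses
import itertools

import dendropy
import numpy as np
import pytest

from plastid_erosion.scenarios import (
    build_parasite_genome,
    rearrangement_scenario,
    small_reference,
)
from plastid_erosion.synteny import (
    all_reversals,
    breakpoint_distance,
    build_lcbs,
    canonical_frame,
    collapse_ir,
    count_tree_rearrangements,
    reversal_distance,
    reversal_distance_lower_bound,
)
from plastid_erosion.synth import DegradationScenario, degrade_plastome

from oracles import bfs_distance_table


def _random_perm(rng, n):
    vals = rng.permutation(np.arange(1, n + 1))
    signs = rng.choice([-1, 1], size=n)
    return tuple(int(v * s) for v, s in zip(vals, signs))


# -- collapse ----------------------------------------------------------

def test_collapse_without_ir_is_identity(parasite):
    from plastid_erosion.genome import QuadripartiteMap
    ref = parasite.reference
    qmap = QuadripartiteMap(len(ref), (0, len(ref)), None, None, None)
    assert collapse_ir(ref, qmap) is ref


def test_collapse_removes_one_ir_copy_and_its_features(parasite):
    col = collapse_ir(parasite.parasite, parasite.qmap_planted)
    assert len(col) == len(parasite.parasite) - parasite.qmap_planted.ir_len
    names = {f.name for f in col.features}
    assert not any(n.endswith("_2") for n in names)
    assert "matK" in names  # IRa copy retained
    # sequence bookkeeping: the retained part is unchanged
    s, e = parasite.qmap_planted.irb
    expect = parasite.parasite.sequence[:s] + parasite.parasite.sequence[e:]
    assert col.sequence == expect


# -- LCBs --------------------------------------------------------------

def test_identical_genomes_form_single_block():
    ref, _ = small_reference(0, n_genes=18)
    twin = dataclasses.replace(ref, id="twin")
    lcb = build_lcbs([ref, twin])
    assert lcb.n_blocks == 1
    assert lcb.permutations() == {"reference": (1,), "twin": (1,)}


def test_single_inversion_gives_three_blocks_with_flipped_middle():
    ref, _ = small_reference(1, n_genes=18)
    names = [f.name for f in ref.features]
    inv, _ = degrade_plastome(
        ref, DegradationScenario(inversions=[(names[6], names[10])]), seed=0)
    inv = dataclasses.replace(inv, id="inv")
    lcb = build_lcbs([ref, inv])
    assert lcb.n_blocks == 3
    perms = lcb.permutations()
    assert perms["reference"] == (1, 2, 3)
    assert perms["inv"] == (1, -2, 3)


def test_multi_genome_blocks_bracket_planted_breakpoints():
    ref, _ = small_reference(2, n_genes=20)
    names = [f.name for f in ref.features]
    genomes = [ref]
    for i, span in enumerate(((names[3], names[7]), (names[12], names[16]))):
        v, _ = degrade_plastome(
            ref, DegradationScenario(inversions=[span]), seed=i)
        genomes.append(dataclasses.replace(v, id=f"v{i}"))
    lcb = build_lcbs(genomes)
    assert lcb.n_blocks == 5
    perms = lcb.permutations()
    assert reversal_distance(perms["v0"], perms["reference"]) == 1
    assert reversal_distance(perms["v0"], perms["v1"]) == 2


def test_disjoint_genomes_rejected():
    a, _ = small_reference(0, n_genes=6)
    b, _ = small_reference(0, n_genes=6)
    b = dataclasses.replace(b, id="other",
                            features=[dataclasses.replace(f, name=f.name + "X")
                                      for f in b.features])
    with pytest.raises(ValueError, match="anchor"):
        build_lcbs([a, b])


# -- distances ---------------------------------------------------------

def test_breakpoint_examples():
    assert breakpoint_distance((1, 2, 3), (1, 2, 3)) == 0
    assert breakpoint_distance((1, -2, 3), (1, 2, 3)) == 2
    assert breakpoint_distance((3, 2, 1), (1, 2, 3)) == 4


def test_breakpoint_matches_adjacency_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(2, 9))
        a, b = _random_perm(rng, n), _random_perm(rng, n)
        # oracle: count signed adjacencies of a (with caps) absent from b
        def adjacencies(p):
            ext = (0,) + p + (n + 1,)
            out = set()
            for x, y in zip(ext, ext[1:]):
                out.add((x, y))
                out.add((-y, -x))
            return out
        d = sum(
            1 for pair in zip((0,) + a + (n + 1,), a + (n + 1,))
            if pair not in adjacencies(b)
        )
        assert breakpoint_distance(a, b) == d


def test_reversal_identity_and_single_event():
    ident = (1, 2, 3, 4, 5)
    assert reversal_distance(ident, ident) == 0
    one = (1, -4, -3, -2, 5)
    assert reversal_distance(one, ident) == 1


def test_reversal_matches_bfs_exhaustively_small_n():
    for n in (2, 3, 4):
        table = bfs_distance_table(n)
        for perm, d in table.items():
            assert reversal_distance(perm) == d


def test_reversal_bounds_and_metric_properties(rng):
    for _ in range(60):
        n = int(rng.integers(2, 8))
        a, b, c = (_random_perm(rng, n) for _ in range(3))
        dab = reversal_distance(a, b)
        bp = breakpoint_distance(a, b)
        assert bp / 2 <= dab <= bp
        assert dab == reversal_distance(b, a)
        assert dab <= reversal_distance(a, c) + reversal_distance(c, b)
        assert reversal_distance_lower_bound(a, b) <= dab


def test_mismatched_block_sets_rejected():
    with pytest.raises(ValueError, match="block set"):
        reversal_distance((1, 2), (1, 2, 3))


def test_canonical_frame_is_rotation_reflection_invariant():
    p = (2, -3, 1, 4)
    rot = (1, 4, 2, -3)
    refl = tuple(-v for v in reversed(p))
    assert canonical_frame(p) == canonical_frame(rot)
    assert canonical_frame(p)[0] == 1


# -- tree --------------------------------------------------------------

def test_identical_leaves_give_zero_total():
    tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
    perm = (1, 2, 3)
    res = count_tree_rearrangements(
        tree, {t: perm for t in "abcd"})
    assert res.total == 0 and res.heuristic


def test_two_leaf_tree_reduces_to_pairwise_distance(rng):
    tree = dendropy.Tree.get(data="(a,b);", schema="newick")
    for _ in range(10):
        pa, pb = _random_perm(rng, 5), _random_perm(rng, 5)
        res = count_tree_rearrangements(tree, {"a": pa, "b": pb})
        assert res.total == reversal_distance(pa, pb)


def test_label_mismatch_rejected():
    tree = dendropy.Tree.get(data="(a,b);", schema="newick")
    with pytest.raises(ValueError, match="labels"):
        count_tree_rearrangements(tree, {"a": (1,), "x": (1,)})


def test_total_invariant_to_leaf_input_order():
    rs = rearrangement_scenario(5)
    base = count_tree_rearrangements(rs.tree, rs.leaf_perms).total
    shuffled = dict(reversed(list(rs.leaf_perms.items())))
    assert count_tree_rearrangements(rs.tree, shuffled).total == base


def test_planted_history_sandwich():
    for seed in range(6):
        rs = rearrangement_scenario(seed)
        res = count_tree_rearrangements(rs.tree, rs.leaf_perms)
        perms = list(rs.leaf_perms.values())
        low = max(
            (reversal_distance(a, b)
             for a, b in itertools.combinations(perms, 2)),
            default=0,
        )
        assert low <= res.total <= max(rs.n_events, low)
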