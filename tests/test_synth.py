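"""Generators: determinism, planted lesions, read simulation, traits."""

import numpy as np
import pandas as pd
import pytest

from plastid_erosion.genome import revcomp
from plastid_erosion.scenarios import random_tree, small_reference
from plastid_erosion.synth import (
    DegradationScenario,
    IRInsertSpec,
    degrade_plastome,
    make_reference_plastome,
    simulate_insert_fragments,
    simulate_reads,
    simulate_traits,
)

_STOPS = {"TAA", "TAG", "TGA"}


def test_reference_is_deterministic_and_complete():
    a, la = make_reference_plastome(seed=7)
    b, _ = make_reference_plastome(seed=7)
    assert a.sequence == b.sequence
    assert len(a.features) == 118  # 82 + 32 + 4
    assert len(la) == 118
    c, _ = make_reference_plastome(seed=8)
    assert c.sequence != a.sequence


def test_reference_protein_genes_are_valid_orfs():
    ref, _ = make_reference_plastome(seed=3)
    for f in ref.features:
        if f.gene_type != "protein":
            continue
        cds = ref.feature_seq(f)
        assert cds.startswith("ATG") and cds[-3:] in _STOPS
        internal = [cds[3 * i:3 * i + 3]
                    for i in range(1, len(cds) // 3 - 1)]
        assert not any(c in _STOPS for c in internal), f.name


def test_empty_scenario_is_identity():
    ref, _ = small_reference(0, n_genes=10)
    out, truth = degrade_plastome(ref, DegradationScenario(), seed=0)
    assert out.sequence == ref.sequence
    assert set(truth.status) == {"intact"}


def test_lesions_have_planted_semantics():
    ref, _ = small_reference(1, n_genes=12)
    proteins = [f.name for f in ref.features if f.gene_type == "protein"]
    sc = DegradationScenario(
        deletions={proteins[0]},
        pseudogenizations={
            proteins[1]: "premature_stop",
            proteins[2]: "frameshift_del",
            proteins[3]: "frameshift_ins",
        },
    )
    out, truth = degrade_plastome(ref, sc, seed=5)
    t = dict(zip(truth.gene, truth.status))
    assert t[proteins[0]] == "absent"
    assert all(t[proteins[i]] == "pseudogene" for i in (1, 2, 3))
    assert proteins[0] not in {f.name for f in out.features}
    # premature stop preserves length; frameshifts change it by 1
    f1 = out.feature_by_name(proteins[1])
    r1 = ref.feature_by_name(proteins[1])
    assert f1.length == r1.length
    cds = out.feature_seq(f1)
    internal = [cds[3 * i:3 * i + 3] for i in range(1, len(cds) // 3 - 1)]
    assert any(c in _STOPS for c in internal)
    assert out.feature_by_name(proteins[2]).length == \
        ref.feature_by_name(proteins[2]).length - 1
    assert out.feature_by_name(proteins[3]).length == \
        ref.feature_by_name(proteins[3]).length + 1


def test_lesion_on_deleted_gene_rejected():
    ref, _ = small_reference(0, n_genes=8)
    g = ref.features[0].name
    sc = DegradationScenario(deletions={g},
                             pseudogenizations={g: "premature_stop"})
    with pytest.raises(ValueError, match="deleted"):
        degrade_plastome(ref, sc, seed=0)


def test_ir_insert_grows_genome_by_exact_reverse_complement():
    ref, _ = small_reference(2, n_genes=20)
    n = len(ref)
    src, L, p = 2000, 9000, 15000
    sc = DegradationScenario(ir_insert=IRInsertSpec(src, L, p))
    out, truth = degrade_plastome(ref, sc, seed=2)
    assert len(out) == n + L
    s0, s1 = truth.attrs["ir_source"]
    c0, c1 = truth.attrs["ir_copy"]
    assert s1 - s0 == c1 - c0 == L
    src_seq = out.sequence[s0:s1]
    copy_seq = out.sequence[c0:c1]
    # junction sealing may touch <= 2 bases adjacent to (not inside) copies
    assert copy_seq == revcomp(src_seq)


def test_inversion_reverses_segment_and_flips_strands():
    ref, _ = small_reference(3, n_genes=12)
    names = [f.name for f in ref.features]
    sc = DegradationScenario(inversions=[(names[4], names[6])])
    out, _ = degrade_plastome(ref, sc, seed=0)
    assert len(out) == len(ref)
    for nm in names[4:7]:
        assert out.feature_by_name(nm).strand != ref.feature_by_name(nm).strand
        assert out.feature_seq(out.feature_by_name(nm)) == \
            ref.feature_seq(ref.feature_by_name(nm))


# -- reads -------------------------------------------------------------

def test_zero_coverage_gives_empty_read_set():
    ref, _ = small_reference(0, n_genes=6)
    rs = simulate_reads(ref, coverage=0, seed=0)
    assert len(rs) == 0


def test_errorfree_reads_are_exact_substrings():
    ref, _ = small_reference(1, n_genes=8)
    rs = simulate_reads(ref, coverage=3, error_rate=0.0, seed=4)
    doubled = ref.sequence + ref.sequence
    for r1, r2 in zip(rs.mate1, rs.mate2):
        assert r1 in doubled or revcomp(r1) in doubled
        assert r2 in doubled or revcomp(r2) in doubled


def test_read_count_matches_target_coverage():
    ref, _ = small_reference(2, n_genes=20)
    cov = 100.0
    rs = simulate_reads(ref, cov, seed=9)
    assert len(rs) == round(cov * len(ref) / (2 * 150))
    realized = sum(len(r) for r in rs.mate1 + rs.mate2) / len(ref)
    assert abs(realized - cov) / cov < 0.05


def test_read_len_longer_than_insert_rejected():
    ref, _ = small_reference(0, n_genes=6)
    with pytest.raises(ValueError, match="insert"):
        simulate_reads(ref, 10, read_len=700, insert_mean=650)


# -- insert fragments --------------------------------------------------

def test_zero_relative_depth_gives_no_fragment_reads():
    ref, _ = small_reference(1, n_genes=10)
    gene = next(f.name for f in ref.features if f.length >= 600)
    rs = simulate_insert_fragments(ref, gene, 0.5, 0.0, 100.0, seed=0)
    assert len(rs) == 0


def test_fragment_reads_confined_to_window_at_expected_depth():
    ref, _ = small_reference(2, n_genes=12)
    feat = next(f for f in ref.features if f.length >= 900)
    cds = ref.feature_seq(feat)
    rs = simulate_insert_fragments(ref, feat.name, fraction=0.5,
                                   relative_depth=0.3, main_coverage=100.0,
                                   seed=1)
    # map reads back onto the CDS by exact search
    hits = []
    for r in rs.mate1 + rs.mate2:
        pos = cds.find(r)
        if pos < 0:
            pos = cds.find(revcomp(r))
        assert pos >= 0
        hits.append((pos, pos + len(r)))
    span = max(e for _, e in hits) - min(s for s, _ in hits)
    assert span <= int(0.5 * len(cds)) + 1
    depth = sum(e - s for s, e in hits) / span
    assert abs(depth - 30.0) / 30.0 < 0.2


def test_fragment_for_unknown_gene_rejected():
    ref, _ = small_reference(0, n_genes=6)
    with pytest.raises(KeyError):
        simulate_insert_fragments(ref, "nosuchgene", 0.5, 0.3, 50.0)


# -- traits ------------------------------------------------------------

def test_zero_length_tree_returns_root_state():
    tree = random_tree(4, seed=0, edge_range=(0.0, 0.0))
    df = simulate_traits(tree, np.eye(2), root_state=(2.5, -1.0), seed=0)
    assert np.allclose(df["x"], 2.5, atol=1e-5)
    assert np.allclose(df["y"], -1.0, atol=1e-5)


def test_single_branch_variance_matches_closed_form():
    import dendropy
    tree = dendropy.Tree.get(data="(a:2.0,b:2.0);", schema="newick")
    reps = simulate_traits(tree, np.eye(2), seed=1, n_reps=4000)
    xs = np.array([df.loc["a", "x"] for df in reps])
    assert abs(xs.var() - 2.0) / 2.0 < 0.1


def test_uncorrelated_rate_matrix_gives_uncorrelated_tips():
    import dendropy
    tree = dendropy.Tree.get(data="(a:1.0,b:1.0);", schema="newick")
    reps = simulate_traits(tree, np.diag([1.0, 2.0]), seed=2, n_reps=10_000)
    dx = np.array([df.loc["a", "x"] - df.loc["b", "x"] for df in reps])
    dy = np.array([df.loc["a", "y"] - df.loc["b", "y"] for df in reps])
    assert abs(np.corrcoef(dx, dy)[0, 1]) < 0.03


def test_non_psd_rate_matrix_rejected():
    tree = random_tree(4, seed=0)
    with pytest.raises(ValueError, match="positive semidefinite"):
        simulate_traits(tree, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0)


def test_generators_reproducible_across_calls():
    ref, _ = small_reference(5, n_genes=10)
    a = simulate_reads(ref, 5, error_rate=0.01, seed=11)
    b = simulate_reads(ref, 5, error_rate=0.01, seed=11)
    assert a.mate1 == b.mate1 and a.mate2 == b.mate2
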