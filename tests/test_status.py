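"""Gene-status classification: alignment, lesion rules, absence checks."""

import numpy as np
import pytest

from plastid_erosion.scenarios import (
    fragment_scenario,
    lesion_scenario,
    small_reference,
)
from plastid_erosion.status import (
    ClassifyConfig,
    GeneStatusCall,
    TargetSearcher,
    align_ortholog,
    build_status_matrix,
    classify_gene,
    verify_absence,
)

from conftest import random_dna


# -- pairwise alignment ------------------------------------------------

def test_identical_sequences_align_perfectly(rng):
    s = random_dna(rng, 300)
    res = align_ortholog(s, s)
    assert res.identity == 100.0
    assert res.n_gap_columns == 0
    assert res.score == 2 * 300


def test_single_deletion_yields_one_gap(rng):
    s = random_dna(rng, 300)
    deleted = s[:143] + s[144:]
    res = align_ortholog(deleted, s)
    assert res.n_gap_columns == 1
    assert res.net_indel == -1


def test_single_deletion_matches_exhaustive_toy_alignment(rng):
    # exhaustive check on tiny pairs: best score over all single-gap
    # placements equals the aligner's score
    for _ in range(5):
        s = random_dna(rng, 14)
        t = s[:6] + s[7:]  # delete one base
        res = align_ortholog(t, s)
        best = -1e9
        for gap_pos in range(len(s)):
            cand = s[:gap_pos] + s[gap_pos + 1:]
            score = sum(2 if a == b else -3 for a, b in zip(cand, t)) - 5
            best = max(best, score)
        assert res.score == best


def test_unrelated_sequences_have_low_identity(rng):
    vals = []
    for _ in range(30):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        vals.append(align_ortholog(a, b).identity)
    assert np.mean(vals) <= 60.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        align_ortholog("", "ACGT")


# -- classification ----------------------------------------------------

def test_planted_lesions_classified_with_named_evidence():
    ls = lesion_scenario(0)
    searcher = TargetSearcher(ls.degraded)
    truth = dict(zip(ls.truth.gene, ls.truth.status))
    lesions = dict(zip(ls.truth.gene, ls.truth.lesion))
    for f in ls.reference.features:
        call = classify_gene(searcher, f, ls.reference)
        assert call.status == truth[f.name], (f.name, call)
        if truth[f.name] == "pseudogene":
            assert call.evidence, f.name
            if lesions[f.name] == "premature_stop":
                assert "premature_stop" in call.evidence
            elif lesions[f.name].startswith("frameshift"):
                assert "frameshift" in call.evidence
        if truth[f.name] == "absent":
            assert "no_homolog" in call.evidence


def test_untouched_genes_are_intact():
    ref, _ = small_reference(4, n_genes=15)
    searcher = TargetSearcher(ref)
    for f in ref.features:
        call = classify_gene(searcher, f, ref)
        assert call.status == "intact"
        assert call.identity == pytest.approx(100.0)


def test_trna_rules_use_identity_and_coverage_only():
    ls = lesion_scenario(1)
    searcher = TargetSearcher(ls.degraded)
    trnas = [f for f in ls.reference.features if f.gene_type == "trna"]
    truth = dict(zip(ls.truth.gene, ls.truth.status))
    for f in trnas:
        call = classify_gene(searcher, f, ls.reference)
        assert call.status == truth[f.name]


def test_pseudogene_requires_evidence_invariant():
    with pytest.raises(ValueError, match="evidence"):
        GeneStatusCall("atpA", "pseudogene", set())
    with pytest.raises(ValueError, match="no_homolog"):
        GeneStatusCall("atpA", "absent", set())


def test_lower_identity_threshold_never_converts_intact_to_absent():
    ls = lesion_scenario(2)
    searcher = TargetSearcher(ls.degraded)
    strict = ClassifyConfig(absent_identity=60.0)
    lax = ClassifyConfig(absent_identity=30.0)
    for f in ls.reference.features:
        a = classify_gene(searcher, f, ls.reference, strict)
        b = classify_gene(searcher, f, ls.reference, lax)
        if a.status == "intact":
            assert b.status != "absent"


def test_invalid_reference_orf_rejected(rng):
    ref, _ = small_reference(0, n_genes=8)
    import dataclasses
    f = next(x for x in ref.features if x.gene_type == "protein")
    broken = dataclasses.replace(f, start=f.start + 1, end=f.end + 1)
    with pytest.raises(ValueError, match="ORF"):
        classify_gene(ref, broken, ref)


# -- absence verification ----------------------------------------------

def test_deleted_gene_without_fragments_confirmed_absent():
    fs = fragment_scenario(3)
    # use only the main reads (drop the planted fragment reads)
    from plastid_erosion.synth import simulate_reads
    main = simulate_reads(fs.degraded, fs.coverage, seed=4)
    v = verify_absence(fs.gene, fs.reference, main, fs.coverage)
    assert v.kind == "confirmed_absent"


def test_planted_fragment_found_below_unit_depth():
    fs = fragment_scenario(4)
    v = verify_absence(fs.gene, fs.reference, fs.reads, fs.coverage)
    assert v.kind == "fragment_found"
    assert v.relative_depth is not None and v.relative_depth < 1.0
    assert v.relative_depth == pytest.approx(fs.relative_depth, rel=0.35)


def test_present_gene_returns_early():
    fs = fragment_scenario(5)
    call = GeneStatusCall("atpA", "intact")
    v = verify_absence(fs.gene, fs.reference, fs.reads, fs.coverage,
                       status_call=call)
    assert v.kind == "present"


def test_nonpositive_coverage_rejected():
    fs = fragment_scenario(6)
    with pytest.raises(ValueError, match="coverage"):
        verify_absence(fs.gene, fs.reference, fs.reads, 0.0)


# -- status matrix -----------------------------------------------------

def test_identical_taxon_gives_all_intact_column():
    ref, _ = small_reference(7, n_genes=12)
    import dataclasses
    twin = dataclasses.replace(ref, id="twin")
    m = build_status_matrix([twin], ref)
    assert (m["twin"] == "intact").all()


def test_matrix_column_matches_truth_table():
    ls = lesion_scenario(8)
    m = build_status_matrix([ls.degraded], ls.reference)
    truth = dict(zip(ls.truth.gene, ls.truth.status))
    col = m[ls.degraded.id]
    assert all(col[g] == truth[g] for g in col.index)
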