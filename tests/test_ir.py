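"""IR candidate detection, coverage, split pairs, and the IR call."""

import numpy as np
import pytest

from plastid_erosion.genome import Plastome, revcomp
from plastid_erosion.ir import (
    IRCallConfig,
    IRCandidate,
    call_ir,
    coverage_profile,
    find_inverted_candidates,
    split_pair_evidence,
)
from plastid_erosion.mapping import PairedPlacements, map_read_set
from plastid_erosion.scenarios import (
    ir_free_scenario,
    planted_ir_scenario,
    small_reference,
)
from plastid_erosion.synteny import collapse_ir
from plastid_erosion.synth import simulate_reads

from conftest import random_dna


def test_no_candidates_in_unstructured_sequence(rng):
    seq = random_dna(rng, 20_000)
    assert find_inverted_candidates(seq, min_len=1000) == []


def test_planted_inverted_pair_found_exactly(rng):
    X = random_dna(rng, 9000)
    seq = random_dna(rng, 3000) + X + random_dna(rng, 4000) + revcomp(X) \
        + random_dna(rng, 3000)
    # seal the junctions: make flanking bases non-complementary
    cands = find_inverted_candidates(seq, min_len=1000)
    assert len(cands) >= 1
    top = cands[0]
    assert top.length >= 9000
    # the planted intervals are contained in the reported maximal ones
    assert top.interval_a[0] <= 3000 and top.interval_a[1] >= 12_000


def test_longer_of_two_planted_irs_reported_first(rng):
    X = random_dna(rng, 5000)
    Y = random_dna(rng, 2000)
    seq = (random_dna(rng, 2500) + X + random_dna(rng, 2500) + Y
           + random_dna(rng, 2500) + revcomp(Y) + random_dna(rng, 2500)
           + revcomp(X) + random_dna(rng, 2500))
    cands = find_inverted_candidates(seq, min_len=1000)
    assert len(cands) >= 2
    assert cands[0].length >= 5000 > cands[1].length >= 2000


def test_min_len_below_50_is_repeat_census_territory(rng):
    with pytest.raises(ValueError, match="census"):
        find_inverted_candidates(random_dna(rng, 1000), min_len=20)


def test_candidate_detection_is_rotation_equivariant():
    sc = planted_ir_scenario(3, ir_len=3000)
    seq = sc.genome.sequence
    n = len(seq)
    base = find_inverted_candidates(seq, min_len=1000)
    off = 12_345
    rot = find_inverted_candidates(seq[off:] + seq[:off], min_len=1000)
    def norm(cands, shift):
        return sorted(
            tuple(sorted(((c.interval_a[0] + shift) % n,
                          (c.interval_b[0] + shift) % n)))
            + (c.length,)
            for c in cands
        )
    assert norm(base, 0) == norm(rot, off)


# -- coverage ----------------------------------------------------------

def test_coverage_profile_trivial_cases():
    empty = PairedPlacements(genome_len=500, read_len=150,
                             insert_mean=650, insert_sd=65)
    assert coverage_profile(empty, 500).depth.sum() == 0

    one = PairedPlacements(
        genome_len=500, read_len=150, insert_mean=650, insert_sd=65,
        pos1=np.array([0]), strand1=np.array(["+"]),
        mapped1=np.array([True]), len1=np.array([150]),
        pos2=np.array([0]), strand2=np.array(["-"]),
        mapped2=np.array([False]), len2=np.array([150]),
    )
    prof = coverage_profile(one, 500)
    assert prof.depth[:150].tolist() == [1] * 150
    assert prof.depth[150:].sum() == 0


def test_coverage_wraps_the_origin():
    p = PairedPlacements(
        genome_len=300, read_len=150, insert_mean=650, insert_sd=65,
        pos1=np.array([250]), strand1=np.array(["+"]),
        mapped1=np.array([True]), len1=np.array([100]),
        pos2=np.array([0]), strand2=np.array(["-"]),
        mapped2=np.array([False]), len2=np.array([100]),
    )
    prof = coverage_profile(p, 300)
    assert prof.depth[250:].tolist() == [1] * 50
    assert prof.depth[:50].tolist() == [1] * 50


def test_collapsed_ir_doubles_coverage():
    sc = planted_ir_scenario(11, ir_len=6000, coverage=60, error_rate=0.0)
    # collapse: remove the copy, map two-copy reads onto the collapsed genome
    from plastid_erosion.genome import partition_quadripartite
    qmap = partition_quadripartite(
        sc.genome, IRCandidate(sc.source, sc.copy))
    collapsed = collapse_ir(sc.genome, qmap)
    pl = map_read_set(sc.reads, collapsed)
    prof = coverage_profile(pl)
    ira = qmap.ira if qmap.ira[0] < qmap.irb[0] else qmap.irb
    # locate the retained copy in collapsed coordinates: IRa keeps its
    # position when IRb (the later interval) is excised
    inside = prof.interval_mean((ira[0] + 500, ira[1] - 500))
    flank = prof.interval_mean((ira[0] - 3000, ira[0] - 500))
    assert 1.7 <= inside / flank <= 2.3


# -- split pairs -------------------------------------------------------

def test_split_pairs_zero_without_ir():
    genome, reads = ir_free_scenario(5, coverage=40)
    pl = map_read_set(reads, genome)
    fake = IRCandidate((2000, 4000), (8000, 10_000))
    ev = split_pair_evidence(pl, fake)
    assert ev.n_split_pairs == 0


def test_all_four_junctions_supported_with_planted_ir():
    sc = planted_ir_scenario(7, coverage=80)
    pl = map_read_set(sc.reads, sc.genome)
    ev = split_pair_evidence(pl, IRCandidate(sc.source, sc.copy))
    assert len(ev.junction_support) == 4
    assert all(v >= 5 for v in ev.junction_support.values())


def test_unpaired_input_rejected():
    p = PairedPlacements(genome_len=100, read_len=10, insert_mean=50,
                         insert_sd=5, pos1=np.array([0, 1]),
                         pos2=np.array([0]))
    with pytest.raises(ValueError, match="unpaired"):
        split_pair_evidence(p, IRCandidate((0, 10), (50, 60)))


# -- the call ----------------------------------------------------------

def test_call_ir_empty_candidates_returns_none():
    assert call_ir([], None, None) is None


def test_call_ir_recovers_planted_boundaries_exactly():
    sc = planted_ir_scenario(2)
    pl = map_read_set(sc.reads, sc.genome)
    cov = coverage_profile(pl)
    cands = find_inverted_candidates(sc.genome.sequence, 1000)
    call = call_ir(cands, cov, lambda c: split_pair_evidence(pl, c))
    assert call is not None and call.method == "split_pairs"
    assert {call.interval_a, call.interval_b} == {sc.source, sc.copy}


def test_short_candidate_rejected_by_min_ir_len():
    cand = IRCandidate((100, 500), (2000, 2400))
    ev = lambda c: None
    assert call_ir([cand], None, ev,
                   IRCallConfig(min_ir_len=1000)) is None


def test_collapsed_candidate_accepted_by_coverage_ratio():
    sc = planted_ir_scenario(11, ir_len=6000, coverage=60, error_rate=0.0)
    from plastid_erosion.genome import partition_quadripartite
    qmap = partition_quadripartite(sc.genome, IRCandidate(sc.source, sc.copy))
    collapsed = collapse_ir(sc.genome, qmap)
    pl = map_read_set(sc.reads, collapsed)
    cov = coverage_profile(pl)
    ira = qmap.ira if qmap.ira[0] < qmap.irb[0] else qmap.irb
    cand = IRCandidate(ira, None)
    call = call_ir([cand], cov, None)
    assert call is not None and call.method == "coverage_ratio"
    assert 1.7 <= call.coverage_ratio <= 2.3
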