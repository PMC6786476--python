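"""Seeded study scenarios with planted ground truth.

``build_parasite_genome`` constructs the package's default degraded
plastome: an 85,318-bp quadripartite genome (LSC 38,859 bp, SSC
27,947 bp, IRs 9,256 bp each) derived from an IR-less 82+32+4 reference,
with 49 protein genes lost or pseudogenized, one tRNA (trnR-CCG)
deleted, and a regained IR carrying trnI-CAU, trnH-GUG, matK, trnK-UUU,
trnQ-UUG, rpl23, rpl2 and rps19.  Fragments of eight deleted genes
(ndhB/D/E/K, petB, psaA/B, psbB) persist as low-depth reads emulating
nuclear/mitochondrial plastid inserts.

The remaining builders produce the smaller randomized scenarios used by
the validation suite: planted-IR genomes with reads, lesion scenarios
for the gene-status classifier, insert-fragment scenarios, planted
rearrangement histories on small trees, and seeded random trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import genes as cat
from .genes import IR_COPY_SUFFIX, IR_SEGMENT_GENES, gene_type_of
from .genome import GeneFeature, Plastome, QuadripartiteMap, revcomp
from .synth import (
    DegradationScenario,
    IRInsertSpec,
    ReadSet,
    _apply_lesion,
    _random_dna,
    degrade_plastome,
    make_reference_plastome,
    simulate_insert_fragments,
    simulate_reads,
)
from .synteny import SignedPerm, all_reversals

# -- parasite design constants (genome bookkeeping of the degraded taxon)
PARASITE_LEN = 85_318
LSC_LEN = 38_859
SSC_LEN = 27_947
IR_LEN = 9_256

# 49 protein genes lost or pseudogenized: photosynthesis-related only
LOST_PROTEINS: frozenset[str] = frozenset(
    [g for g in cat.PROTEIN_GENES if g[:3] in ("psa", "psb", "pet", "ndh")]
    + ["ycf12", "rbcL", "chlB", "chlL", "chlN",
       "atpF", "atpH", "atpI", "ycf3", "ycf4", "cemA", "ccsA"]
)

# the subset retained as pseudogenes (the rest are physically deleted)
PSEUDOGENIZED: dict[str, str] = {
    "chlB": "premature_stop", "chlL": "frameshift_del",
    "chlN": "premature_stop",
    "psbA": "premature_stop", "psbC": "frameshift_ins",
    "psbD": "premature_stop", "psbE": "frameshift_del",
    "psaC": "premature_stop", "psaI": "frameshift_ins",
    "petA": "premature_stop", "petD": "frameshift_del",
    "petG": "premature_stop",
    "atpF": "frameshift_ins", "atpH": "premature_stop",
    "atpI": "frameshift_del",
    "ndhA": "premature_stop", "ndhC": "frameshift_ins",
    "ndhH": "premature_stop",
    "ycf3": "frameshift_del", "ycf4": "premature_stop",
    "rbcL": "frameshift_del",
}

DELETED_PROTEINS: frozenset[str] = LOST_PROTEINS - set(PSEUDOGENIZED)
DELETED_TRNA = "trnR-CCG"

# deleted genes whose fragments persist in other genomic compartments
FRAGMENT_GENES: tuple[str, ...] = (
    "ndhB", "ndhD", "ndhE", "ndhK", "petB", "psaA", "psaB", "psbB",
)

assert len(LOST_PROTEINS) == 49, len(LOST_PROTEINS)
assert len(PSEUDOGENIZED) == 21
assert len(DELETED_PROTEINS) == 28
assert set(FRAGMENT_GENES) <= DELETED_PROTEINS


@dataclass
class ParasiteScenario:
    reference: Plastome
    parasite: Plastome
    truth: pd.DataFrame
    qmap_planted: QuadripartiteMap
    fragment_depths: dict[str, float] = field(default_factory=dict)


def _assemble_region(
    rng: np.random.Generator,
    gene_seqs: list[tuple[str, str, str]],  # (name, seq reading-orient, strand)
    target_len: int,
    min_spacer: int = 40,
) -> tuple[str, list[GeneFeature]]:
    """Concatenate genes with random spacers summing to an exact length."""
    genes_bp = sum(len(s) for _, s, _ in gene_seqs)
    k = len(gene_seqs) + 1
    spacer_total = target_len - genes_bp
    if spacer_total < k * min_spacer:
        raise ValueError(
            f"region target {target_len} too small for {genes_bp} gene bp"
        )
    w = rng.random(k) + 0.5
    lens = np.floor(w / w.sum() * spacer_total).astype(int)
    lens[0] += spacer_total - int(lens.sum())
    parts = []
    feats = []
    pos = 0
    for i, (name, seq, strand) in enumerate(gene_seqs):
        sp = _random_dna(rng, int(lens[i]))
        parts.append(sp)
        pos += len(sp)
        parts.append(revcomp(seq) if strand == "-" else seq)
        feats.append(GeneFeature(name, pos, pos + len(seq), strand))
        pos += len(seq)
    parts.append(_random_dna(rng, int(lens[-1])))
    return "".join(parts), feats


def build_parasite_genome(seed: int = 0) -> ParasiteScenario:
    """The default degraded plastome with planted quadripartite truth."""
    rng = np.random.default_rng(seed)
    reference, _ = make_reference_plastome(seed=seed)

    removed = set(DELETED_PROTEINS) | {DELETED_TRNA}
    retained = [f for f in reference.features if f.name not in removed]

    seqs: dict[str, str] = {}
    status: dict[str, tuple[str, str]] = {}
    for f in retained:
        s = reference.feature_seq(f)
        if f.name in PSEUDOGENIZED:
            lesion = PSEUDOGENIZED[f.name]
            s = _apply_lesion(s, lesion, rng)
            status[f.name] = ("pseudogene", lesion)
        else:
            status[f.name] = ("intact", "")
        seqs[f.name] = s
    for g in sorted(removed):
        status[g] = ("absent", "deleted")

    ir_names = list(IR_SEGMENT_GENES)
    sc_names = [f.name for f in retained if f.name not in ir_names]
    # rRNAs live in the SSC; fill the rest proportionally by gene length,
    # preserving reference gene order and strands within each region
    ssc_set = {g for g in sc_names if gene_type_of(g) == "rrna"}
    rest = [g for g in sc_names if g not in ssc_set]
    sc_bp = sum(len(seqs[g]) for g in sc_names)
    ssc_gene_target = SSC_LEN / (LSC_LEN + SSC_LEN) * sc_bp
    acc = sum(len(seqs[g]) for g in ssc_set)
    for g in reversed(rest):
        if acc >= ssc_gene_target:
            break
        ssc_set.add(g)
        acc += len(seqs[g])
    ssc_names = [g for g in sc_names if g in ssc_set]
    lsc_names = [g for g in sc_names if g not in ssc_set]

    ref_strand = {f.name: f.strand for f in reference.features}

    def gene_tuples(names):
        return [(g, seqs[g], ref_strand[g]) for g in names]

    lsc_seq, lsc_feats = _assemble_region(rng, gene_tuples(lsc_names), LSC_LEN)
    ira_seq, ira_feats = _assemble_region(rng, gene_tuples(ir_names), IR_LEN)
    ssc_seq, ssc_feats = _assemble_region(rng, gene_tuples(ssc_names), SSC_LEN)
    irb_seq = revcomp(ira_seq)

    feats: list[GeneFeature] = []
    feats.extend(lsc_feats)
    for f in ira_feats:
        feats.append(GeneFeature(f.name, LSC_LEN + f.start, LSC_LEN + f.end,
                                 f.strand))
    off = LSC_LEN + IR_LEN
    for f in ssc_feats:
        feats.append(GeneFeature(f.name, off + f.start, off + f.end, f.strand))
    off = LSC_LEN + IR_LEN + SSC_LEN
    for f in ira_feats:
        s = off + (IR_LEN - f.end)
        feats.append(
            GeneFeature(f.name + IR_COPY_SUFFIX, s, s + f.length,
                        "+" if f.strand == "-" else "-")
        )
        status[f.name + IR_COPY_SUFFIX] = status[f.name]

    seq = list(lsc_seq + ira_seq + ssc_seq + irb_seq)
    assert len(seq) == PARASITE_LEN
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    other = {"A": "C", "C": "A", "G": "T", "T": "G"}
    # seal IR junctions so the planted boundaries are maximal
    if seq[LSC_LEN - 1] == comp[seq[0]]:
        seq[LSC_LEN - 1] = other[seq[LSC_LEN - 1]]
    i_first_ssc = LSC_LEN + IR_LEN
    i_last_ssc = LSC_LEN + IR_LEN + SSC_LEN - 1
    if seq[i_first_ssc] == comp[seq[i_last_ssc]]:
        seq[i_first_ssc] = other[seq[i_first_ssc]]

    for f in feats:
        f.status = status[f.name][0]
    parasite = Plastome("parasite", "".join(seq), True, sorted(
        feats, key=lambda f: f.start))
    qmap = QuadripartiteMap(
        PARASITE_LEN,
        (0, LSC_LEN),
        (LSC_LEN + IR_LEN, LSC_LEN + IR_LEN + SSC_LEN),
        (LSC_LEN, LSC_LEN + IR_LEN),
        (LSC_LEN + IR_LEN + SSC_LEN, PARASITE_LEN),
    )
    truth = pd.DataFrame(
        [{"gene": g, "status": st, "lesion": le}
         for g, (st, le) in sorted(status.items())]
    )
    frag_depths = {
        g: float(rng.uniform(0.2, 0.6)) for g in FRAGMENT_GENES
    }
    return ParasiteScenario(reference, parasite, truth, qmap, frag_depths)


def parasite_read_set(
    sc: ParasiteScenario,
    coverage: float = 60.0,
    error_rate: float = 0.002,
    seed: int = 0,
) -> ReadSet:
    """Shotgun reads of the parasite plus its planted insert fragments."""
    reads = simulate_reads(sc.parasite, coverage, error_rate=error_rate,
                           seed=seed)
    for i, (g, rel) in enumerate(sorted(sc.fragment_depths.items())):
        frag = simulate_insert_fragments(
            sc.reference, g, fraction=0.5, relative_depth=rel,
            main_coverage=coverage, error_rate=error_rate, seed=seed + 17 + i,
        )
        reads.extend(frag)
    return reads


# ---------------------------------------------------------------------
# randomized small scenarios
# ---------------------------------------------------------------------

_BIG = ("rpoC2", "ycf1", "ycf2", "rpoB", "psaA", "psaB", "ndhF",
        "rrn16", "rrn23")
_SMALL_PROTEINS = tuple(
    g for g in cat.PROTEIN_GENES if g not in _BIG
)
_SMALL_GENES = _SMALL_PROTEINS  # retained for callers wanting proteins only


def small_reference(seed: int, n_genes: int = 30, intergenic: int = 400):
    """A compact mixed-complement reference: ~2/3 protein genes,
    ~1/4 tRNAs, plus the two short rRNAs when room allows."""
    n_trna = max(2, n_genes // 4)
    n_rrna = 2 if n_genes >= 12 else 0
    n_prot = n_genes - n_trna - n_rrna
    names: list[str] = []
    prot = list(_SMALL_PROTEINS[:n_prot])
    trna = list(cat.TRNA_GENES[:n_trna])
    rrna = ["rrn5", "rrn4.5"][:n_rrna]
    # interleave so deletions/inversions touch mixed neighborhoods
    while prot or trna or rrna:
        progressed = False
        for _ in range(3):
            if prot:
                names.append(prot.pop(0))
                progressed = True
        if trna:
            names.append(trna.pop(0))
            progressed = True
        if rrna and (len(names) % 7 == 0 or not progressed):
            names.append(rrna.pop(0))
    return make_reference_plastome(tuple(names), intergenic, seed)


@dataclass
class PlantedIRScenario:
    genome: Plastome
    reads: ReadSet
    source: tuple[int, int]
    copy: tuple[int, int]
    coverage: float
    error_rate: float


def planted_ir_scenario(
    seed: int,
    ir_len: int | None = None,
    coverage: float | None = None,
    error_rate: float | None = None,
) -> PlantedIRScenario:
    """A genome with one planted IR (2-12 kb) plus 50-100x reads."""
    rng = np.random.default_rng(seed)
    base, _ = small_reference(seed, n_genes=30)
    n = len(base)
    if ir_len is None:
        ir_len = int(rng.integers(2000, 12001))
    ir_len = min(ir_len, n - 8000)
    margin = 2500
    src_start = int(rng.integers(margin, n - ir_len - 2 * margin))
    insert_pos = int(
        rng.integers(src_start + ir_len + margin, n - margin + 1)
    )
    scenario = DegradationScenario(
        ir_insert=IRInsertSpec(src_start, ir_len, insert_pos)
    )
    genome, table = degrade_plastome(base, scenario, seed=seed)
    cov = float(rng.uniform(50, 100)) if coverage is None else coverage
    err = float(rng.uniform(0, 0.01)) if error_rate is None else error_rate
    reads = simulate_reads(genome, cov, error_rate=err, seed=seed + 1)
    return PlantedIRScenario(
        genome, reads, tuple(table.attrs["ir_source"]),
        tuple(table.attrs["ir_copy"]), cov, err,
    )


def ir_free_scenario(seed: int, coverage: float = 60.0):
    """A genome without any large IR, with reads."""
    genome, _ = small_reference(seed, n_genes=24)
    rng = np.random.default_rng(seed)
    err = float(rng.uniform(0, 0.01))
    reads = simulate_reads(genome, coverage, error_rate=err, seed=seed + 1)
    return genome, reads


@dataclass
class LesionScenario:
    reference: Plastome
    degraded: Plastome
    truth: pd.DataFrame
    scenario: DegradationScenario


def lesion_scenario(seed: int, n_deletions: int = 4,
                    n_pseudo: int = 7) -> LesionScenario:
    """>= 10 planted lesions: deletions plus mixed pseudogenizations."""
    rng = np.random.default_rng(seed)
    reference, _ = small_reference(seed, n_genes=32)
    proteins = [f.name for f in reference.features
                if f.gene_type == "protein"]
    others = [f.name for f in reference.features
              if f.gene_type != "protein"]
    picked = list(rng.choice(proteins, size=n_pseudo + max(0, n_deletions - 2),
                             replace=False))
    pseudo = {
        g: ("premature_stop", "frameshift_del", "frameshift_ins")[i % 3]
        for i, g in enumerate(picked[:n_pseudo])
    }
    deletions = set(picked[n_pseudo:])
    if others and n_deletions >= 2:
        deletions |= set(rng.choice(others, size=min(2, len(others)),
                                    replace=False))
    scenario = DegradationScenario(deletions=deletions,
                                   pseudogenizations=pseudo)
    degraded, truth = degrade_plastome(reference, scenario, seed=seed)
    return LesionScenario(reference, degraded, truth, scenario)


@dataclass
class FragmentScenario:
    reference: Plastome
    degraded: Plastome
    gene: str
    reads: ReadSet
    coverage: float
    relative_depth: float
    fraction: float


def fragment_scenario(seed: int, coverage: float = 40.0) -> FragmentScenario:
    """A deleted gene whose fragments persist at low relative depth."""
    rng = np.random.default_rng(seed)
    reference, _ = small_reference(seed, n_genes=14)
    proteins = [f for f in reference.features if f.gene_type == "protein"
                and f.length >= 600]
    gene = proteins[int(rng.integers(0, len(proteins)))].name
    scenario = DegradationScenario(deletions={gene})
    degraded, _ = degrade_plastome(reference, scenario, seed=seed)
    rel = float(rng.uniform(0.2, 0.6))
    frac = float(rng.uniform(0.4, 0.8))
    reads = simulate_reads(degraded, coverage, seed=seed + 1)
    frag = simulate_insert_fragments(
        reference, gene, fraction=frac, relative_depth=rel,
        main_coverage=coverage, seed=seed + 2,
    )
    reads.extend(frag)
    return FragmentScenario(reference, degraded, gene, reads, coverage,
                            rel, frac)


# ---------------------------------------------------------------------
# trees and rearrangement histories
# ---------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int,
                edge_range: tuple[float, float] = (0.3, 1.5)) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths."""
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for t in ns:
        leaf = dendropy.Node(taxon=t)
        leaf.edge.length = float(rng.uniform(*edge_range))
        nodes.append(leaf)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(*edge_range))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    for x in nodes:
        tree.seed_node.add_child(x)
    if len(nodes) == 1:
        tree.seed_node = nodes[0]
    return tree


@dataclass
class RearrangementScenario:
    tree: dendropy.Tree
    leaf_perms: dict[str, SignedPerm]
    n_events: int


def rearrangement_scenario(seed: int, n_taxa: int = 6,
                           n_blocks: int = 7) -> RearrangementScenario:
    """Inversions planted along the branches of a random tree.

    Each branch carries 0-2 reversals (mean ~0.7); the root's block
    order is the identity.
    """
    rng = np.random.default_rng(seed)
    tree = random_tree(n_taxa, seed)
    identity: SignedPerm = tuple(range(1, n_blocks + 1))
    labels: dict[int, SignedPerm] = {}
    n_events = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            labels[id(node)] = identity
            continue
        perm = labels[id(node.parent_node)]
        k = min(2, int(rng.poisson(0.7)))
        for _ in range(k):
            moves = all_reversals(perm)
            perm = moves[int(rng.integers(0, len(moves)))]
        n_events += k
        labels[id(node)] = perm
    leaf_perms = {
        leaf.taxon.label: labels[id(leaf)]
        for leaf in tree.leaf_node_iter()
    }
    return RearrangementScenario(tree, leaf_perms, n_events)
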