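"""Intact / pseudogene / absent classification of reference genes.

A gene is located in the target genome by exact 21-mer seeds of its
reference coding sequence (both strands), the best seed cluster is
aligned globally (affine gaps, free end gaps on the genomic window), and
lesion rules are applied:

* protein genes are intact when the homolog covers >= 90% of the CDS,
  carries no stop codon before 90% of the reference protein length, and
  has a net indel of 0 mod 3 (reading frame restored);
* a premature stop, frame-breaking indel, or truncation makes it a
  pseudogene — every pseudogene call names at least one lesion;
* tRNA/rRNA genes have no reading frame: covered fraction >= 90% and
  identity >= 80% suffice;
* a gene with no homologous region at >= 60% identity over >= 30% of the
  CDS is absent.

Absences can be verified against the read pool: fragments of deleted
genes that persist in other genomic compartments (nuclear/mitochondrial
inserts) show up as short matches at well below the plastome's depth —
the synthetic counterpart of finding orthologs on contigs with
k-mer coverage below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .genome import GeneFeature, Plastome, revcomp
from .synth import ReadSet

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ClassifyConfig:
    covered_intact: float = 0.9     # min covered CDS fraction for intact
    stop_frac: float = 0.9          # stop before this protein fraction = lesion
    absent_identity: float = 60.0   # % identity floor for any homolog
    absent_covered: float = 0.3     # covered fraction floor for any homolog
    trna_identity: float = 80.0     # % identity for intact tRNA/rRNA
    seed_k: int = 21


@dataclass
class GeneStatusCall:
    gene: str
    status: str
    evidence: set[str] = field(default_factory=set)
    identity: float = 0.0           # percent over aligned core
    covered_fraction: float = 0.0
    fragment_relative_depth: float | None = None

    def __post_init__(self):
        if self.status == "pseudogene" and not self.evidence:
            raise ValueError("pseudogene call without lesion evidence")
        if self.status == "absent" and "no_homolog" not in self.evidence:
            raise ValueError("absent call without no_homolog evidence")


@dataclass
class AlignmentResult:
    score: float
    identity: float          # percent over aligned core columns
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_gap_columns: int
    net_indel: int           # target core length - query core length
    target_core: str         # target sequence aligned to the query core


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    # the genomic window may extend past the CDS on both sides: skipping
    # target flanks (deletions at the ends) is free
    a.end_deletion_score = 0.0
    return a


def align_ortholog(target_region: str, reference_cds: str) -> AlignmentResult:
    """Global affine-gap alignment of a reference CDS into a genomic window.

    End gaps on the genomic window are free; identity is computed over the
    aligned core (first to last aligned reference base).
    """
    if not target_region or not reference_cds:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(target_region, reference_cds)[0]
    blocks_t, blocks_q = aln.aligned
    if len(blocks_q) == 0:
        return AlignmentResult(aln.score, 0.0, 0, 0, 0, 0, 0, 0, "")
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    t_start, t_end = int(blocks_t[0][0]), int(blocks_t[-1][1])
    matches = 0
    block_len = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        tseq = target_region[ts:te]
        qseq = reference_cds[qs:qe]
        matches += sum(1 for x, y in zip(tseq, qseq) if x == y)
        block_len += te - ts
    t_core = t_end - t_start
    q_core = q_end - q_start
    gap_cols = (t_core - block_len) + (q_core - block_len)
    columns = block_len + gap_cols
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentResult(
        aln.score, identity, q_start, q_end, t_start, t_end, gap_cols,
        t_core - q_core, target_region[t_start:t_end],
    )


class TargetSearcher:
    """Seed index of a target genome for CDS homolog location."""

    def __init__(self, target: Plastome, k: int = 21):
        self.target = target
        self.k = k
        self.n = len(target)
        doubled = target.sequence + target.sequence
        self.doubled = doubled
        idx: dict[str, list[int]] = {}
        for i in range(self.n):
            idx.setdefault(doubled[i:i + k], []).append(i)
        self.index = idx

    def best_window(self, cds: str, margin: int = 80):
        """(window sequence, strand) for the best seed cluster, or None."""
        k, n = self.k, self.n
        best = None  # (n_seeds, -span, strand, lo, hi)
        for strand, q in (("+", cds), ("-", revcomp(cds))):
            # cluster seed hits by diagonal
            clusters: dict[int, list[tuple[int, int]]] = {}
            for off in range(0, max(1, len(q) - k + 1), 7):
                for p in self.index.get(q[off:off + k], ()):
                    d = (p - off) % n
                    # merge diagonals within a small band
                    keyd = None
                    for cand in (d - 2, d - 1, d, d + 1, d + 2):
                        if cand % n in clusters:
                            keyd = cand % n
                            break
                    if keyd is None:
                        keyd = d
                    clusters.setdefault(keyd, []).append((p, off))
            for d, hits in clusters.items():
                tpos = [p for p, _ in hits]
                lo = min(tpos) - margin
                hi = max(p + k for p, _ in hits) + margin
                # pad to the full CDS extent around the seeds
                qlo = min(off for _, off in hits)
                qhi = max(off + k for _, off in hits)
                lo -= qlo + 40
                hi += len(q) - qhi + 40
                cand = (len(hits), -(hi - lo), strand, lo, hi)
                if best is None or cand > best:
                    best = cand
        if best is None:
            return None
        _, _, strand, lo, hi = best
        lo = max(lo, 0) if hi - lo >= self.n else lo
        length = min(hi - lo, self.n)
        window = self.doubled[lo % self.n: lo % self.n + length]
        return window, strand


def classify_gene(
    target: Plastome | TargetSearcher,
    gene: GeneFeature | str,
    reference: Plastome,
    config: ClassifyConfig = ClassifyConfig(),
) -> GeneStatusCall:
    """Classify one reference gene in the target plastome."""
    searcher = (
        target if isinstance(target, TargetSearcher)
        else TargetSearcher(target, config.seed_k)
    )
    feat = (
        reference.feature_by_name(gene) if isinstance(gene, str) else gene
    )
    cds = reference.feature_seq(feat)
    is_protein = feat.gene_type == "protein"
    if is_protein and (not cds.startswith("ATG") or len(cds) % 3 != 0):
        raise ValueError(f"reference ORF for {feat.name} is invalid")

    found = searcher.best_window(cds)
    if found is None:
        return GeneStatusCall(feat.name, "absent", {"no_homolog"})
    window, strand = found
    if strand == "-":
        window = revcomp(window)
    res = align_ortholog(window, cds)
    covered = (res.q_end - res.q_start) / len(cds)
    if res.identity < config.absent_identity or covered < config.absent_covered:
        return GeneStatusCall(feat.name, "absent", {"no_homolog"},
                              res.identity, covered)

    evidence: set[str] = set()
    if covered < config.covered_intact:
        evidence.add("truncated")
    if not is_protein:
        if res.identity < config.trna_identity:
            evidence.add("truncated")
        status = "intact" if not evidence else "pseudogene"
        return GeneStatusCall(feat.name, status, evidence, res.identity,
                              covered)

    if res.net_indel % 3 != 0:
        evidence.add("frameshift")
    # reconstruct the target coding sequence in the reference frame and
    # look for a stop before ``stop_frac`` of the protein
    recon = cds[:res.q_start] + res.target_core + cds[res.q_end:]
    ref_protein_len = len(cds) // 3 - 1
    limit = int(config.stop_frac * ref_protein_len)
    for c in range(1, min(limit, len(recon) // 3)):
        if recon[3 * c:3 * c + 3] in _STOPS:
            evidence.add("premature_stop")
            break
    status = "intact" if not evidence else "pseudogene"
    return GeneStatusCall(feat.name, status, evidence, res.identity, covered)


# ---------------------------------------------------------------------
# absence verification against reads
# ---------------------------------------------------------------------

@dataclass
class AbsenceVerdict:
    kind: str                      # confirmed_absent | fragment_found | present
    span: tuple[int, int] | None = None   # CDS coordinates covered
    relative_depth: float | None = None


def verify_absence(
    gene: GeneFeature | str,
    reference: Plastome,
    reads: ReadSet,
    main_coverage: float,
    status_call: GeneStatusCall | None = None,
    min_identity: float = 0.8,
    min_span: int = 50,
    seed_k: int = 21,
) -> AbsenceVerdict:
    """Search the read pool for fragments of an absent gene's CDS.

    Reports the covered span of the CDS and its depth relative to the
    main plastome coverage; relative depth < 1 flags a likely
    extra-plastomic (nuclear/mitochondrial) insert.
    """
    if main_coverage <= 0:
        raise ValueError("main_coverage must be positive")
    if status_call is not None and status_call.status != "absent":
        return AbsenceVerdict("present")
    feat = reference.feature_by_name(gene) if isinstance(gene, str) else gene
    cds = reference.feature_seq(feat)
    idx: dict[str, list[int]] = {}
    for i in range(0, len(cds) - seed_k + 1):
        idx.setdefault(cds[i:i + seed_k], []).append(i)
    depth = np.zeros(len(cds), dtype=float)
    for read in _iter_reads(reads):
        for r in (read, revcomp(read)):
            placed = False
            for off in range(0, max(1, len(r) - seed_k + 1), seed_k // 2):
                for p in idx.get(r[off:off + seed_k], ()):
                    d = p - off  # read position 0 maps to CDS position d
                    lo = max(0, d)
                    hi = min(len(cds), d + len(r))
                    if hi - lo < min_span:
                        continue
                    rseg = r[lo - d:hi - d]
                    cseg = cds[lo:hi]
                    matches = sum(1 for x, y in zip(rseg, cseg) if x == y)
                    if matches >= min_identity * (hi - lo):
                        depth[lo:hi] += 1
                        placed = True
                        break
                if placed:
                    break
            if placed:
                break
    covered = np.flatnonzero(depth > 0)
    if len(covered) == 0:
        return AbsenceVerdict("confirmed_absent")
    span = (int(covered[0]), int(covered[-1]) + 1)
    rel = float(depth[span[0]:span[1]].mean()) / main_coverage
    return AbsenceVerdict("fragment_found", span, rel)


def _iter_reads(reads: ReadSet):
    yield from reads.mate1
    yield from reads.mate2


# ---------------------------------------------------------------------
# status matrix
# ---------------------------------------------------------------------

def build_status_matrix(
    targets: list[Plastome],
    reference: Plastome,
    config: ClassifyConfig = ClassifyConfig(),
) -> pd.DataFrame:
    """Gene x taxon matrix of {intact, pseudogene, absent}."""
    genes = [f.name for f in reference.features]
    data = {}
    for t in targets:
        searcher = TargetSearcher(t, config.seed_k)
        data[t.id] = [
            classify_gene(searcher, g, reference, config).status
            for g in genes
        ]
    return pd.DataFrame(data, index=genes)
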