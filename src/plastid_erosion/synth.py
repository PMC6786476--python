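"""Synthetic plastome, read-set and trait generators with planted truth.

Every generator is deterministic given its seed.  The default
"parasite" scenario emulates the degradation syndrome of a heterotrophic
conifer plastome: loss of 49 photosynthesis-related protein genes and one
tRNA from an 82+32+4 reference complement, pseudogenization by premature
stops and 1-bp frameshifts, a regained ~9.3-kb inverted repeat carrying
LSC-typical genes, and low-depth "insert" fragments of deleted genes that
mimic nuclear/mitochondrial copies of plastid DNA.

Planted IR junctions are *sealed*: the generator mutates at most one
intergenic base adjacent to each junction so that the inverted self-match
cannot extend past the planted boundary.  Without sealing, the planted
boundary would differ from the maximal-match boundary with probability
1 - (3/4)^4 per scenario and boundary recovery would be ill-posed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genes as gene_catalog
from .genes import IR_COPY_SUFFIX, gene_type_of
from .genome import GeneFeature, Plastome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

# real-ish lengths (bp) for a few size-outlier genes; everything else is
# drawn from a per-type range
_GENE_LEN_OVERRIDES = {
    "rpoC2": 4200, "ycf1": 5100, "ycf2": 6801, "ndhF": 2220,
    "psaA": 2253, "psaB": 2205, "psbA": 1062, "psbB": 1527,
    "psbC": 1386, "psbD": 1062, "rbcL": 1428, "matK": 1530,
    "rpoB": 3213, "rpoC1": 2046, "atpA": 1524, "atpB": 1497,
    "rpl2": 828, "rpl23": 282, "rps19": 279, "accD": 1482,
    "chlB": 1527, "chlL": 873, "chlN": 1410, "ccsA": 960,
    "rrn16": 1491, "rrn23": 2811, "rrn4.5": 103, "rrn5": 121,
}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _gene_length(rng: np.random.Generator, name: str) -> int:
    if name in _GENE_LEN_OVERRIDES:
        return _GENE_LEN_OVERRIDES[name]
    t = gene_type_of(name)
    if t == "trna":
        return int(rng.integers(71, 91))
    if t == "rrna":
        return int(rng.integers(110, 130))
    return 3 * int(rng.integers(40, 181)) + 6  # ATG + codons + stop


def _protein_seq(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_CODONS, size=n_codons))
    return "ATG" + body + "TAA"


def _gene_seq(rng: np.random.Generator, name: str) -> str:
    length = _gene_length(rng, name)
    if gene_type_of(name) == "protein":
        return _protein_seq(rng, length)
    return _random_dna(rng, length)


# ---------------------------------------------------------------------
# reference plastome
# ---------------------------------------------------------------------

def make_reference_plastome(
    gene_names: tuple[str, ...] | None = None,
    intergenic_len: int = 400,
    seed: int = 0,
) -> tuple[Plastome, pd.DataFrame]:
    """Build an IR-less photosynthetic reference plastome.

    Genes (default: the full 82+32+4 catalog) are laid down in catalog
    order on alternating random strands, separated by random intergenic
    spacers of mean ``intergenic_len``.  Protein genes are valid ORFs
    (ATG start, no internal stop, TAA stop).  Returns the plastome plus a
    truth ledger with one row per gene.
    """
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = gene_catalog.reference_gene_order()
    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    for name in gene_names:
        spacer = int(rng.integers(max(50, intergenic_len // 2),
                                  intergenic_len * 3 // 2 + 1))
        parts.append(_random_dna(rng, spacer))
        pos += spacer
        seq = _gene_seq(rng, name)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(revcomp(seq) if strand == "-" else seq)
        feats.append(GeneFeature(name, pos, pos + len(seq), strand,
                                 status="intact"))
        pos += len(seq)
    parts.append(_random_dna(rng, int(rng.integers(
        max(50, intergenic_len // 2), intergenic_len * 3 // 2 + 1))))
    plastome = Plastome("reference", "".join(parts), True, feats)
    ledger = pd.DataFrame(
        {
            "gene": [f.name for f in feats],
            "gene_class": [f.gene_class for f in feats],
            "strand": [f.strand for f in feats],
            "start": [f.start for f in feats],
            "end": [f.end for f in feats],
            "status": "intact",
            "lesion": "",
        }
    )
    return plastome, ledger


# ---------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------

@dataclass
class IRInsertSpec:
    """Duplicate ``[source_start, source_start+length)`` in inverted
    orientation, inserting the copy at ``insert_pos`` (a position in the
    pre-insertion coordinate system, outside the source interval)."""

    source_start: int
    length: int
    insert_pos: int


@dataclass
class DegradationScenario:
    deletions: set[str] = field(default_factory=set)
    pseudogenizations: dict[str, str] = field(default_factory=dict)
    ir_insert: IRInsertSpec | None = None
    inversions: list[tuple[str, str]] = field(default_factory=list)
    insert_fragments: list[tuple[str, float, float]] = field(
        default_factory=list
    )  # (gene, fraction of CDS, relative depth)

    def validate(self, reference: Plastome) -> None:
        names = {f.name for f in reference.features}
        for g in self.deletions | set(self.pseudogenizations):
            if g not in names:
                raise ValueError(f"scenario targets unknown gene {g!r}")
        overlap = self.deletions & set(self.pseudogenizations)
        if overlap:
            raise ValueError(f"lesion on deleted gene(s): {sorted(overlap)}")
        for g, _, _ in self.insert_fragments:
            if g not in names:
                raise ValueError(f"insert fragment for unknown gene {g!r}")


_LESIONS = ("premature_stop", "frameshift_del", "frameshift_ins")


def _apply_lesion(cds: str, lesion: str, rng: np.random.Generator) -> str:
    """Mutate a coding sequence (given in reading orientation)."""
    n_codons = len(cds) // 3
    if lesion == "premature_stop":
        c = int(rng.integers(max(1, n_codons // 5), max(2, (7 * n_codons) // 10)))
        return cds[: 3 * c] + "TAA" + cds[3 * c + 3:]
    pos = int(rng.integers(len(cds) // 5, (7 * len(cds)) // 10))
    if lesion == "frameshift_del":
        return cds[:pos] + cds[pos + 1:]
    if lesion == "frameshift_ins":
        return cds[:pos] + _random_dna(rng, 1) + cds[pos:]
    raise ValueError(f"unknown lesion {lesion!r}")


def _splice(seq: str, start: int, end: int, replacement: str) -> str:
    return seq[:start] + replacement + seq[end:]


def _shift_features(
    feats: list[GeneFeature], at: int, delta: int
) -> list[GeneFeature]:
    out = []
    for f in feats:
        if f.start >= at:
            out.append(dataclasses.replace(f, start=f.start + delta,
                                           end=f.end + delta))
        else:
            out.append(f)
    return out


def _seal_ir_junctions(
    seq_list: list[str], src: tuple[int, int], copy: tuple[int, int]
) -> None:
    """Break inverted-match extension past the planted IR boundaries.

    Mutates ``seq_list`` (a list of single characters) in place.  Indices
    are taken modulo the genome length (circular genome).
    """
    n = len(seq_list)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def other(b: str) -> str:
        return {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[b]

    # right of source pairs with left of copy
    a = src[1] % n
    b = (copy[0] - 1) % n
    if seq_list[b] == comp[seq_list[a]]:
        seq_list[b] = other(seq_list[b])
    # left of source pairs with right of copy
    a = (src[0] - 1) % n
    b = copy[1] % n
    if seq_list[b] == comp[seq_list[a]]:
        seq_list[b] = other(seq_list[b])


def degrade_plastome(
    reference: Plastome,
    scenario: DegradationScenario,
    seed: int = 0,
) -> tuple[Plastome, pd.DataFrame]:
    """Apply a degradation scenario; returns the plastome plus truth table.

    Lesion semantics: ``premature_stop`` replaces one internal codon with
    TAA; ``frameshift_del``/``frameshift_ins`` remove/add one base inside
    the CDS; deletions excise the gene plus its flanking intergenic DNA
    (to the midpoint of each spacer); ``ir_insert`` duplicates a segment
    in inverted orientation elsewhere (with sealed junctions); inversions
    reverse-complement the span from one gene to another including their
    flanks.  The truth table records the intended per-gene status.
    """
    scenario.validate(reference)
    rng = np.random.default_rng(seed)
    seq = reference.sequence
    feats = [dataclasses.replace(f) for f in reference.features]
    truth: dict[str, tuple[str, str]] = {
        f.name: ("intact", "") for f in feats
    }

    def by_name(name: str) -> GeneFeature:
        for f in feats:
            if f.name == name:
                return f
        raise KeyError(name)

    # 1. pseudogenizations (may change length by +-1)
    for name in sorted(scenario.pseudogenizations):
        lesion = scenario.pseudogenizations[name]
        if lesion not in _LESIONS:
            raise ValueError(f"unknown lesion {lesion!r} for {name}")
        f = by_name(name)
        cds = seq[f.start:f.end]
        if f.strand == "-":
            cds = revcomp(cds)
        new_cds = _apply_lesion(cds, lesion, rng)
        block = revcomp(new_cds) if f.strand == "-" else new_cds
        delta = len(new_cds) - (f.end - f.start)
        seq = _splice(seq, f.start, f.end, block)
        if delta:
            feats = _shift_features(feats, f.end, delta)
        f = by_name(name)
        f.end = f.start + len(new_cds)
        truth[name] = ("pseudogene", lesion)

    # 2. deletions (gene plus flanking intergenic halves)
    for name in sorted(scenario.deletions, key=lambda g: -by_name(g).start):
        f = by_name(name)
        order = sorted(feats, key=lambda x: x.start)
        i = order.index(f)
        prev_end = order[i - 1].end if i > 0 else 0
        next_start = order[i + 1].start if i + 1 < len(order) else len(seq)
        cut_lo = (prev_end + f.start) // 2
        cut_hi = (f.end + next_start) // 2
        seq = _splice(seq, cut_lo, cut_hi, "")
        feats = [x for x in feats if x.name != name]
        feats = _shift_features(feats, cut_hi, cut_lo - cut_hi)
        truth[name] = ("absent", "deleted")

    # 3. inversions (span from gene_from to gene_to, spacer midpoints)
    for g_from, g_to in scenario.inversions:
        fa, fb = by_name(g_from), by_name(g_to)
        if fa.start > fb.start:
            fa, fb = fb, fa
        order = sorted(feats, key=lambda x: x.start)
        ia, ib = order.index(fa), order.index(fb)
        prev_end = order[ia - 1].end if ia > 0 else 0
        next_start = order[ib + 1].start if ib + 1 < len(order) else len(seq)
        lo = (prev_end + fa.start) // 2
        hi = (fb.end + next_start) // 2
        seq = _splice(seq, lo, hi, revcomp(seq[lo:hi]))
        for f in feats:
            if lo <= f.start and f.end <= hi:
                s = lo + (hi - f.end)
                f.start, f.end = s, s + f.length
                f.strand = "+" if f.strand == "-" else "-"

    # 4. IR insertion
    if scenario.ir_insert is not None:
        ins = scenario.ir_insert
        s0, L, p = ins.source_start, ins.length, ins.insert_pos
        if s0 <= p < s0 + L:
            raise ValueError("IR insertion point inside the source interval")
        segment = seq[s0:s0 + L]
        copy = revcomp(segment)
        seq = _splice(seq, p, p, copy)
        feats = _shift_features(feats, p, L)
        src = (s0 + L, s0 + 2 * L) if p <= s0 else (s0, s0 + L)
        copy_iv = (p, p + L)
        # duplicate features fully inside the source
        dup = []
        for f in feats:
            if src[0] <= f.start and f.end <= src[1]:
                off_end = src[1] - f.end
                ns = copy_iv[0] + off_end
                dup.append(
                    GeneFeature(
                        f.name + IR_COPY_SUFFIX, ns, ns + f.length,
                        "+" if f.strand == "-" else "-",
                        f.gene_class, f.status,
                    )
                )
                truth[f.name + IR_COPY_SUFFIX] = truth[f.name]
        feats.extend(dup)
        chars = list(seq)
        _seal_ir_junctions(chars, src, copy_iv)
        seq = "".join(chars)

    feats.sort(key=lambda f: f.start)
    for f in feats:
        f.status = truth[f.name][0]
    out = Plastome(reference.id + "_degraded", seq, reference.circular, feats)
    rows = []
    for name, (status, lesion) in truth.items():
        rows.append({"gene": name, "status": status, "lesion": lesion})
    table = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
    if scenario.ir_insert is not None:
        table.attrs["ir_source"] = src
        table.attrs["ir_copy"] = copy_iv
    return out, table


# ---------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------

@dataclass
class ReadSet:
    """Paired-end reads; mate 2 is the reverse-complement side."""

    mate1: list[str]
    mate2: list[str]
    read_len: int
    insert_mean: float
    insert_sd: float
    error_rate: float
    seed: int
    frag_start: np.ndarray = field(default_factory=lambda: np.array([], int))
    frag_len: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __len__(self) -> int:
        return len(self.mate1)

    def extend(self, other: "ReadSet") -> None:
        self.mate1.extend(other.mate1)
        self.mate2.extend(other.mate2)
        self.frag_start = np.concatenate([self.frag_start, other.frag_start])
        self.frag_len = np.concatenate([self.frag_len, other.frag_len])

    def write_fastq(self, prefix: str) -> tuple[str, str]:
        paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
        for path, reads, suffix in zip(paths, (self.mate1, self.mate2),
                                       ("/1", "/2")):
            with open(path, "w") as fh:
                for i, r in enumerate(reads):
                    fh.write(f"@read{i}{suffix}\n{r}\n+\n{'I' * len(r)}\n")
        return paths


def _add_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    plastome: Plastome,
    coverage: float,
    read_len: int = 150,
    insert_mean: float = 650.0,
    insert_sd: float = 65.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform paired-end shotgun reads from a circular genome.

    Number of pairs = round(coverage * genome_len / (2 * read_len));
    fragment lengths are Gaussian truncated below at ``read_len``.
    With ``error_rate`` 0, every read is an exact substring of the doubled
    genome or its reverse complement.
    """
    if read_len > insert_mean:
        raise ValueError("read_len exceeds mean insert size")
    if coverage < 0:
        raise ValueError("negative coverage")
    rng = np.random.default_rng(seed)
    n = len(plastome)
    n_pairs = int(round(coverage * n / (2 * read_len)))
    doubled = plastome.sequence + plastome.sequence
    m1, m2 = [], []
    starts = np.empty(n_pairs, dtype=int)
    lens = np.empty(n_pairs, dtype=int)
    for i in range(n_pairs):
        flen = int(np.clip(rng.normal(insert_mean, insert_sd), read_len, n))
        fstart = int(rng.integers(0, n))
        frag = doubled[fstart:fstart + flen]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if rng.random() < 0.5:
            r1, r2 = r2, r1
        m1.append(_add_errors(r1, rng, error_rate))
        m2.append(_add_errors(r2, rng, error_rate))
        starts[i] = fstart
        lens[i] = flen
    return ReadSet(m1, m2, read_len, insert_mean, insert_sd, error_rate,
                   seed, starts, lens)


def simulate_insert_fragments(
    reference: Plastome,
    gene: str,
    fraction: float,
    relative_depth: float,
    main_coverage: float,
    read_len: int = 150,
    insert_mean: float = 650.0,
    insert_sd: float = 65.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Reads from a contiguous fraction of one gene at reduced depth.

    Emulates nuclear/mitochondrial copies of plastid genes: the fragment
    window covers ``fraction`` of the CDS and is sequenced at
    ``relative_depth * main_coverage``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    feat = reference.feature_by_name(gene)
    cds = reference.feature_seq(feat)
    win_len = max(read_len, int(round(fraction * len(cds))))
    win_len = min(win_len, len(cds))
    win_start = int(rng.integers(0, len(cds) - win_len + 1))
    window = cds[win_start:win_start + win_len]
    depth = relative_depth * main_coverage
    n_pairs = int(round(depth * win_len / (2 * read_len)))
    m1, m2 = [], []
    starts = np.empty(n_pairs, dtype=int)
    lens = np.empty(n_pairs, dtype=int)
    for i in range(n_pairs):
        flen = int(np.clip(rng.normal(insert_mean, insert_sd), read_len,
                           win_len))
        fstart = int(rng.integers(0, win_len - flen + 1))
        frag = window[fstart:fstart + flen]
        r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
        if rng.random() < 0.5:
            r1, r2 = r2, r1
        m1.append(_add_errors(r1, rng, error_rate))
        m2.append(_add_errors(r2, rng, error_rate))
        starts[i] = fstart
        lens[i] = flen
    rs = ReadSet(m1, m2, read_len, insert_mean, insert_sd, error_rate,
                 seed, starts, lens)
    rs.frag_start = starts  # window-relative; truth only
    return rs


# ---------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------

def simulate_traits(
    tree,
    rate_matrix: np.ndarray,
    root_state: np.ndarray | tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    n_reps: int = 1,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Simulate correlated Brownian-motion traits on a tree.

    Tip values are multivariate normal with covariance R (x) C where C is
    the shared-path-length matrix of the tree.  Returns a DataFrame (tips
    as index, columns x and y), or a list of them when n_reps > 1.
    """
    from .traits import tree_covariance

    R = np.asarray(rate_matrix, float)
    if R.shape != (2, 2) or abs(R[0, 1] - R[1, 0]) > 1e-12:
        raise ValueError("rate matrix must be symmetric 2x2")
    eig = np.linalg.eigvalsh(R)
    if eig[0] < -1e-10:
        raise ValueError("rate matrix is not positive semidefinite")
    taxa, C = tree_covariance(tree)
    n = len(taxa)
    rng = np.random.default_rng(seed)
    # sample via independent factor structure: chol(R) (x) chol(C)
    jitter = 1e-12 * max(1.0, float(np.trace(C)) / max(n, 1))
    Lc = np.linalg.cholesky(C + jitter * np.eye(n))
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0, None)
    Lr = V @ np.diag(np.sqrt(w))
    mu = np.asarray(root_state, float)
    out = []
    for _ in range(n_reps):
        Z = rng.standard_normal((2, n))
        X = Lr @ Z @ Lc.T  # rows: traits, cols: tips
        df = pd.DataFrame(
            {"x": mu[0] + X[0], "y": mu[1] + X[1]}, index=taxa
        )
        out.append(df)
    return out[0] if n_reps == 1 else out
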