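"""Core plastome domain types and standard-format I/O.

Coordinates are 0-based half-open internally.  Features on a circular
genome may span the origin; such an interval is stored with
``start > end`` is *not* used — instead ``end`` may exceed the genome
length and all extraction is done modulo the length (the same convention
is used in the emitted GFF3, where an origin-spanning gene has
``end > sequence length``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import base_name, gene_class_of, gene_type_of

STATUSES = ("intact", "pseudogene", "absent", "unclassified")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneFeature:
    """A gene on a plastome.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length for an origin-spanning feature on a circular genome.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    gene_class: str = ""
    status: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.gene_class:
            self.gene_class = gene_class_of(self.name)
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r} for {self.name}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def gene_type(self) -> str:
        return gene_type_of(self.name)


@dataclass
class Plastome:
    """A (usually circular) plastid genome with its gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValueError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
            if f.start < 0 or f.start >= n:
                raise ValueError(f"feature {f.name} start {f.start} out of range")
            if f.end > n and not self.circular:
                raise ValueError(f"feature {f.name} exceeds linear genome")
            if f.end > 2 * n:
                raise ValueError(f"feature {f.name} wraps more than once")

    # -- sequence access ------------------------------------------------
    def extract(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps the origin when end > length."""
        n = len(self.sequence)
        start %= n
        if end <= n and end > start:
            return self.sequence[start:end]
        # wrapped: read off the doubled sequence
        length = end - start if end > start else end + n - start
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def feature_seq(self, feat: GeneFeature) -> str:
        s = self.extract(feat.start, feat.end)
        return revcomp(s) if feat.strand == "-" else s

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def rotated(self, offset: int) -> "Plastome":
        """Return a copy with the origin moved to ``offset``."""
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            start = (f.start - offset) % n
            feats.append(dataclasses.replace(f, start=start, end=start + f.length))
        return Plastome(self.id, seq, self.circular, feats)


@dataclass
class QuadripartiteMap:
    """LSC/SSC/IRa/IRb intervals partitioning a circular genome.

    Intervals are (start, end) 0-based half-open, possibly wrapping
    (end > genome length).  ``ira``/``irb`` are ``None`` for an IR-less
    genome, in which case ``lsc`` spans everything and ``ssc`` is None.
    """

    genome_len: int
    lsc: tuple[int, int]
    ssc: tuple[int, int] | None
    ira: tuple[int, int] | None
    irb: tuple[int, int] | None

    def _ilen(self, iv: tuple[int, int] | None) -> int:
        return 0 if iv is None else iv[1] - iv[0]

    @property
    def lsc_len(self) -> int:
        return self._ilen(self.lsc)

    @property
    def ssc_len(self) -> int:
        return self._ilen(self.ssc)

    @property
    def ir_len(self) -> int:
        return self._ilen(self.ira)

    @property
    def has_ir(self) -> bool:
        return self.ira is not None

    def __post_init__(self) -> None:
        if (self.ira is None) != (self.irb is None):
            raise ValueError("ira and irb must both be present or both absent")
        if self.ira is not None:
            if self._ilen(self.ira) != self._ilen(self.irb):
                raise ValueError("IR copies differ in length")
            total = self.lsc_len + self.ssc_len + 2 * self.ir_len
            if total != self.genome_len:
                raise ValueError(
                    f"regions sum to {total}, genome is {self.genome_len}"
                )
        else:
            if self.lsc_len != self.genome_len:
                raise ValueError("degenerate map must span the genome")

    def to_dict(self) -> dict:
        return {
            "genome_len": self.genome_len,
            "lsc": list(self.lsc),
            "ssc": list(self.ssc) if self.ssc else None,
            "ira": list(self.ira) if self.ira else None,
            "irb": list(self.irb) if self.irb else None,
            "lsc_len": self.lsc_len,
            "ssc_len": self.ssc_len,
            "ir_len": self.ir_len,
        }


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_genome(
    path_fasta: str | Path,
    path_features: str | Path | None = None,
    circular: bool = True,
) -> Plastome:
    """Load a plastome from FASTA plus GFF3 or 3-column TSV features.

    GFF3 coordinates are 1-based inclusive; TSV columns are
    ``name<TAB>start<TAB>end[<TAB>strand]`` with the same convention.
    """
    records = list(SeqIO.parse(str(path_fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    features: list[GeneFeature] = []
    if path_features is not None:
        path_features = Path(path_features)
        if path_features.suffix.lower() in (".gff", ".gff3"):
            features = _read_gff3(path_features)
        else:
            features = _read_tsv(path_features)
    return Plastome(rec.id, str(rec.seq), circular, features)


def _read_gff3(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] != "gene":
            continue
        start_1, end_1 = int(cols[3]), int(cols[4])
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID")
        if not name:
            raise ValueError(f"gene line without Name attribute: {line}")
        feats.append(
            GeneFeature(
                name=name,
                start=start_1 - 1,
                end=end_1,
                strand=cols[6] if cols[6] in "+-" else "+",
                gene_class=attrs.get("gene_class", ""),
                status=attrs.get("status", "unclassified"),
            )
        )
    return feats


def _read_tsv(path: Path) -> list[GeneFeature]:
    feats = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        name, start_1, end_1 = cols[0], int(cols[1]), int(cols[2])
        strand = cols[3] if len(cols) > 3 else "+"
        feats.append(GeneFeature(name, start_1 - 1, end_1, strand))
    return feats


def write_genome(
    plastome: Plastome,
    path_fasta: str | Path,
    path_gff: str | Path | None = None,
) -> None:
    """Write FASTA and (optionally) GFF3 with 1-based inclusive coordinates."""
    rec = SeqRecord(Seq(plastome.sequence), id=plastome.id, description="")
    SeqIO.write([rec], str(path_fasta), "fasta")
    if path_gff is None:
        return
    lines = ["##gff-version 3",
             f"##sequence-region {plastome.id} 1 {len(plastome)}"]
    for f in plastome.features:
        attrs = (
            f"ID={f.name};Name={f.name};gene_class={f.gene_class};"
            f"status={f.status}"
        )
        lines.append(
            "\t".join(
                [
                    plastome.id, "plastid_erosion", "gene",
                    str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
                ]
            )
        )
    Path(path_gff).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# Summaries and partitioning
# ---------------------------------------------------------------------

def summarize_coding_capacity(plastome: Plastome) -> dict:
    """Counts of intact / pseudogene / absent unique genes.

    IR-duplicated copies are deduplicated by base name; a gene counts as
    intact if any copy is intact, else pseudogene if any copy is one.
    Raises if any feature is still unclassified.
    """
    per_gene: dict[str, str] = {}
    per_gene_class: dict[str, str] = {}
    for f in plastome.features:
        if f.status == "unclassified":
            raise ValueError(f"feature {f.name} is unclassified")
        b = base_name(f.name)
        rank = {"intact": 0, "pseudogene": 1, "absent": 2}
        if b not in per_gene or rank[f.status] < rank[per_gene[b]]:
            per_gene[b] = f.status
            per_gene_class[b] = f.gene_class

    by_type: dict[str, dict[str, int]] = {
        t: {"intact": 0, "pseudogene": 0, "absent": 0}
        for t in ("protein", "trna", "rrna")
    }
    by_class: dict[str, dict[str, int]] = {}
    for gene, status in per_gene.items():
        by_type[gene_type_of(gene)][status] += 1
        cls = per_gene_class[gene]
        by_class.setdefault(
            cls, {"intact": 0, "pseudogene": 0, "absent": 0}
        )[status] += 1

    totals = {
        s: sum(by_type[t][s] for t in by_type)
        for s in ("intact", "pseudogene", "absent")
    }
    return {
        "by_type": by_type,
        "by_class": by_class,
        "totals": totals,
        "unique_genes": len(per_gene),
        "unique_intact": totals["intact"],
    }


def _circular_gaps(
    n: int, iv_a: tuple[int, int], iv_b: tuple[int, int]
) -> list[tuple[int, int]]:
    """The two single-copy intervals between two disjoint circular intervals."""
    gaps = []
    for left, right in ((iv_a, iv_b), (iv_b, iv_a)):
        start = left[1] % n
        end = right[0] % n
        length = (end - start) % n
        gaps.append((start, start + length))
    return gaps


def _intervals_overlap(n: int, a: tuple[int, int], b: tuple[int, int]) -> bool:
    pa = set(range(a[0], a[1]))
    pb = {p % n for p in range(b[0], b[1])}
    return bool({p % n for p in pa} & pb)


def partition_quadripartite(plastome: Plastome, ir_call) -> QuadripartiteMap:
    """Partition the genome into LSC/SSC/IRa/IRb given an IR call.

    ``ir_call`` provides ``interval_a``/``interval_b`` (or is None for an
    IR-less genome).  The longer single-copy gap is labelled LSC; ties are
    broken toward the region with more protein-coding features.
    """
    n = len(plastome)
    if ir_call is None:
        return QuadripartiteMap(n, (0, n), None, None, None)
    iv_a = tuple(ir_call.interval_a)
    iv_b = tuple(ir_call.interval_b)
    if _intervals_overlap(n, iv_a, iv_b):
        raise ValueError("IR intervals overlap")
    gap1, gap2 = _circular_gaps(n, iv_a, iv_b)
    len1, len2 = gap1[1] - gap1[0], gap2[1] - gap2[0]
    if len1 > len2:
        lsc, ssc = gap1, gap2
    elif len2 > len1:
        lsc, ssc = gap2, gap1
    else:  # tie: more protein-coding features wins
        def n_protein(iv):
            return sum(
                1
                for f in plastome.features
                if f.gene_type == "protein"
                and iv[0] <= f.start % n < iv[1] % n + (n if iv[1] > n else 0)
            )
        lsc, ssc = (gap1, gap2) if n_protein(gap1) >= n_protein(gap2) else (gap2, gap1)
    # order the IR copies so that ira follows the LSC
    if (iv_a[0] - lsc[1]) % n < (iv_b[0] - lsc[1]) % n:
        ira, irb = iv_a, iv_b
    else:
        ira, irb = iv_b, iv_a
    return QuadripartiteMap(n, lsc, ssc, ira, irb)
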