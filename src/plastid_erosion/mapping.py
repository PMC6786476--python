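"""Minimal internal read mapper for simulated reads.

Exact 31-mer seed anchoring plus ungapped extension, ties broken by
leftmost genome position.  This is sufficient for reads simulated with
substitution errors only; real data would go through an external mapper,
whose placements can be supplied via the SAM subset reader below
(QNAME, FLAG, RNAME, POS, CIGAR with a single M run, PNEXT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Plastome, revcomp
from .synth import ReadSet


@dataclass
class PairedPlacements:
    """Mapped positions for a paired read set (arrays indexed by pair)."""

    genome_len: int
    read_len: int
    insert_mean: float
    insert_sd: float
    # per-mate arrays; pos is the leftmost genome coordinate (mod n)
    pos1: np.ndarray = field(default_factory=lambda: np.array([], int))
    strand1: np.ndarray = field(default_factory=lambda: np.array([], "U1"))
    mapped1: np.ndarray = field(default_factory=lambda: np.array([], bool))
    len1: np.ndarray = field(default_factory=lambda: np.array([], int))
    pos2: np.ndarray = field(default_factory=lambda: np.array([], int))
    strand2: np.ndarray = field(default_factory=lambda: np.array([], "U1"))
    mapped2: np.ndarray = field(default_factory=lambda: np.array([], bool))
    len2: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __len__(self) -> int:
        return len(self.pos1)


class GenomeIndex:
    """Exact k-mer index over the doubled (circular) genome."""

    def __init__(self, genome: Plastome, k: int = 31):
        self.k = k
        self.n = len(genome)
        self.seq = genome.sequence
        self.arr = np.frombuffer(
            (genome.sequence + genome.sequence).encode(), dtype=np.uint8
        )
        index: dict[str, list[int]] = {}
        doubled = genome.sequence + genome.sequence
        for i in range(self.n):
            index.setdefault(doubled[i:i + k], []).append(i)
        self.index = index

    def place_read(self, read: str, min_identity: float = 0.85):
        """Best ungapped placement: (pos, strand, score) or None."""
        k, n = self.k, self.n
        L = len(read)
        if L < k:
            return None
        best = None  # (-score, pos, strand)
        for strand, seq in (("+", read), ("-", revcomp(read))):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            cands: set[int] = set()
            for off in (0, L - k, (L - k) // 2):
                for p in self.index.get(seq[off:off + k], ()):
                    cands.add((p - off) % n)
            for pos in cands:
                score = int(np.count_nonzero(self.arr[pos:pos + L] == arr))
                key = (-score, pos, strand)
                if best is None or key < best:
                    best = key
        if best is None or -best[0] < min_identity * L:
            return None
        return best[1], best[2], -best[0]


def map_read_set(
    reads: ReadSet,
    genome: Plastome,
    k: int = 31,
    min_identity: float = 0.85,
) -> PairedPlacements:
    """Place every mate of a paired read set on the genome."""
    idx = GenomeIndex(genome, k)
    n_pairs = len(reads)
    out = PairedPlacements(
        genome_len=idx.n,
        read_len=reads.read_len,
        insert_mean=reads.insert_mean,
        insert_sd=reads.insert_sd,
    )
    for mate, seqs in ((1, reads.mate1), (2, reads.mate2)):
        pos = np.zeros(n_pairs, int)
        strand = np.full(n_pairs, "+", dtype="U1")
        mapped = np.zeros(n_pairs, bool)
        lens = np.zeros(n_pairs, int)
        for i, r in enumerate(seqs):
            hit = idx.place_read(r, min_identity)
            if hit is not None:
                pos[i], strand[i] = hit[0], hit[1]
                mapped[i] = True
            lens[i] = len(r)
        if mate == 1:
            out.pos1, out.strand1, out.mapped1, out.len1 = pos, strand, mapped, lens
        else:
            out.pos2, out.strand2, out.mapped2, out.len2 = pos, strand, mapped, lens
    return out


# ---------------------------------------------------------------------
# SAM subset I/O
# ---------------------------------------------------------------------

def write_sam(placements: PairedPlacements, reads: ReadSet,
              rname: str, path: str | Path) -> None:
    lines = [f"@HD\tVN:1.6\tSO:unsorted",
             f"@SQ\tSN:{rname}\tLN:{placements.genome_len}"]
    for i in range(len(placements)):
        for mate in (1, 2):
            pos = placements.pos1[i] if mate == 1 else placements.pos2[i]
            strand = placements.strand1[i] if mate == 1 else placements.strand2[i]
            mapped = placements.mapped1[i] if mate == 1 else placements.mapped2[i]
            seq = reads.mate1[i] if mate == 1 else reads.mate2[i]
            opos = placements.pos2[i] if mate == 1 else placements.pos1[i]
            flag = 1 | (64 if mate == 1 else 128)
            if not mapped:
                flag |= 4
            if strand == "-":
                flag |= 16
            lines.append(
                "\t".join(
                    [
                        f"read{i}", str(flag), rname,
                        str(int(pos) + 1), "60", f"{len(seq)}M", "=",
                        str(int(opos) + 1), "0", seq, "I" * len(seq),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sam(path: str | Path) -> PairedPlacements:
    """Parse the SAM subset written by :func:`write_sam`."""
    genome_len = 0
    rows: dict[str, dict[int, tuple[int, str, bool, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("@"):
            if line.startswith("@SQ"):
                for tag in line.split("\t")[1:]:
                    if tag.startswith("LN:"):
                        genome_len = int(tag[3:])
            continue
        cols = line.split("\t")
        qname, flag, pos = cols[0], int(cols[1]), int(cols[3]) - 1
        mate = 1 if flag & 64 else 2
        strand = "-" if flag & 16 else "+"
        mapped = not (flag & 4)
        m = int(cols[5].rstrip("M")) if cols[5].endswith("M") else len(cols[9])
        rows.setdefault(qname, {})[mate] = (pos, strand, mapped, m)
    names = sorted(rows, key=lambda s: int(s.replace("read", "") or 0))
    n = len(names)
    out = PairedPlacements(genome_len=genome_len, read_len=0,
                           insert_mean=650.0, insert_sd=65.0)
    for mate in (1, 2):
        pos = np.zeros(n, int)
        strand = np.full(n, "+", dtype="U1")
        mapped = np.zeros(n, bool)
        lens = np.zeros(n, int)
        for i, q in enumerate(names):
            if mate in rows[q]:
                pos[i], strand[i], mapped[i], lens[i] = rows[q][mate]
        if mate == 1:
            out.pos1, out.strand1, out.mapped1, out.len1 = pos, strand, mapped, lens
        else:
            out.pos2, out.strand2, out.mapped2, out.len2 = pos, strand, mapped, lens
    out.read_len = int(lens.max()) if n else 0
    return out
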