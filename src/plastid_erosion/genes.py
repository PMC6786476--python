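"""Plastid gene catalog and gene-class assignment.

The catalog mirrors a typical photosynthetic Podocarpaceae (conifer)
plastome complement: 82 protein-coding genes, 32 tRNAs and 4 rRNAs.
Gene classes are assigned by gene-symbol prefix; the table can be
overridden by passing a custom mapping to :func:`gene_class_of`.
"""

from __future__ import annotations

# Protein-coding complement (82 genes).
PROTEIN_GENES: tuple[str, ...] = (
    # photosystem I
    "psaA", "psaB", "psaC", "psaI", "psaJ",
    # photosystem II (ycf12 = psb30 is a PSII subunit in conifers)
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ", "ycf12",
    # cytochrome b6/f
    "petA", "petB", "petD", "petG", "petL", "petN",
    # ATP synthase
    "atpA", "atpB", "atpE", "atpF", "atpH", "atpI",
    # NAD(P)H dehydrogenase complex
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
    "ndhI", "ndhJ", "ndhK",
    # Rubisco large subunit
    "rbcL",
    # light-independent chlorophyll biosynthesis
    "chlB", "chlL", "chlN",
    # plastid-encoded RNA polymerase
    "rpoA", "rpoB", "rpoC1", "rpoC2",
    # small ribosomal subunit proteins
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
    "rps15", "rps18", "rps19",
    # large ribosomal subunit proteins
    "rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32",
    "rpl33", "rpl36",
    # other conserved ORFs
    "matK", "infA", "clpP", "accD", "ccsA", "cemA", "ycf1", "ycf2",
    "ycf3", "ycf4",
)

TRNA_GENES: tuple[str, ...] = (
    "trnA-UGC", "trnC-GCA", "trnD-GUC", "trnE-UUC", "trnF-GAA",
    "trnfM-CAU", "trnG-GCC", "trnG-UCC", "trnH-GUG", "trnI-CAU",
    "trnI-GAU", "trnK-UUU", "trnL-CAA", "trnL-UAA", "trnL-UAG",
    "trnM-CAU", "trnN-GUU", "trnP-UGG", "trnP-GGG", "trnQ-UUG",
    "trnR-ACG", "trnR-CCG", "trnR-UCU", "trnS-GCU", "trnS-GGA",
    "trnS-UGA", "trnT-GGU", "trnT-UGU", "trnV-GAC", "trnV-UAC",
    "trnW-CCA", "trnY-GUA",
)

RRNA_GENES: tuple[str, ...] = ("rrn16", "rrn23", "rrn4.5", "rrn5")

ALL_GENES: tuple[str, ...] = PROTEIN_GENES + TRNA_GENES + RRNA_GENES

#: prefix -> gene_class lookup, checked longest-prefix-first
CLASS_PREFIXES: dict[str, str] = {
    "psa": "photosystem",
    "psb": "photosystem",
    "pet": "cytochrome_b6f",
    "atp": "atp_synthase",
    "ndh": "ndh",
    "rbc": "rubisco",
    "chl": "chl",
    "rpo": "rpo",
    "rpl": "ribosomal_protein",
    "rps": "ribosomal_protein",
    "trn": "trna",
    "rrn": "rrna",
}

GENE_CLASSES: tuple[str, ...] = (
    "photosystem", "cytochrome_b6f", "atp_synthase", "ndh", "rubisco",
    "chl", "rpo", "ribosomal_protein", "trna", "rrna", "other",
)

#: suffix appended to the second copy of a gene duplicated inside an IR
IR_COPY_SUFFIX = "_2"


def gene_class_of(name: str, overrides: dict[str, str] | None = None) -> str:
    """Return the gene class for a gene symbol (IR copy suffixes ignored)."""
    base = base_name(name)
    if overrides and base in overrides:
        return overrides[base]
    for prefix in sorted(CLASS_PREFIXES, key=len, reverse=True):
        if base.startswith(prefix):
            return CLASS_PREFIXES[prefix]
    return "other"


def gene_type_of(name: str) -> str:
    """Coarse gene type: 'protein', 'trna' or 'rrna'."""
    cls = gene_class_of(name)
    if cls in ("trna", "rrna"):
        return cls
    return "protein"


def base_name(name: str) -> str:
    """Strip an IR copy suffix, if present."""
    if name.endswith(IR_COPY_SUFFIX):
        return name[: -len(IR_COPY_SUFFIX)]
    return name


# --- default layout used by the synthetic reference generator ----------
# The eight genes the degraded genome's novel IR carries, kept adjacent in
# the reference so a single contiguous segment can be duplicated.
IR_SEGMENT_GENES: tuple[str, ...] = (
    "trnI-CAU", "trnH-GUG", "matK", "trnK-UUU", "trnQ-UUG",
    "rpl23", "rpl2", "rps19",
)


def reference_gene_order() -> tuple[str, ...]:
    """Catalog order with the IR-destined genes grouped contiguously."""
    rest = [g for g in ALL_GENES if g not in IR_SEGMENT_GENES]
    # place the IR block roughly a third of the way in
    cut = len(rest) // 3
    return tuple(rest[:cut]) + IR_SEGMENT_GENES + tuple(rest[cut:])
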