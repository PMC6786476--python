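"""End-to-end pipeline: simulate -> detect IR -> partition -> gene status
-> repeats -> synteny -> traits -> report.

Every stage writes its outputs before the next starts; a run manifest
records parameters, seeds, and per-stage outputs.  All randomness flows
from one top-level seed through fixed per-stage offsets, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import partition_quadripartite, summarize_coding_capacity, \
    write_genome
from .ir import IRCallConfig, call_ir, coverage_profile, \
    find_inverted_candidates, split_pair_evidence
from .mapping import map_read_set
from .repeats import find_maximal_repeats, find_tandem_repeats, \
    repeat_density
from .scenarios import build_parasite_genome, parasite_read_set, \
    random_tree
from .status import ClassifyConfig, TargetSearcher, classify_gene, \
    verify_absence
from .synteny import build_lcbs, breakpoint_distance, collapse_ir, \
    count_tree_rearrangements, reversal_distance
from .synth import DegradationScenario, degrade_plastome, simulate_traits
from .traits import lrt_correlation, tree_covariance


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    coverage: float = 60.0
    error_rate: float = 0.002
    # stage thresholds (defaults follow the standard parameterization:
    # repeats min 20 bp / Hamming 3 / e <= 1e-3, tandems >= 10 bp with
    # 2-50 bp units, IR >= 1 kb with >= 5 pairs per junction)
    min_ir_len: int = 1000
    min_pairs: int = 5
    repeat_min_len: int = 20
    repeat_max_mismatch: int = 3
    repeat_max_evalue: float = 1e-3
    tandem_min_total: int = 10
    tandem_unit_range: tuple[int, int] = (2, 50)
    min_block_len: int = 0
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    # optional file-driven inputs (traits stage needs the tree)
    tree_file: str | None = None
    traits_file: str | None = None
    n_trait_taxa: int = 16
    # stages to run; detect-ir/partition/gene-status always run after
    # simulate, the heavier censuses can be deselected
    stages: tuple[str, ...] = ("repeats", "synteny", "traits")

    def validate(self) -> None:
        if self.traits_file and not self.tree_file:
            raise ValueError(
                "configuration error: traits table supplied without a tree"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "classify" in data:
            data["classify"] = ClassifyConfig(**data["classify"])
        if "tandem_unit_range" in data:
            data["tandem_unit_range"] = tuple(data["tandem_unit_range"])
        return cls(**data)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the default synthetic scenario; return manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("classify", "out_dir")
        },
        "stages": {},
    }

    # 1. simulate ------------------------------------------------------
    sc = build_parasite_genome(seed=config.seed)
    reads = parasite_read_set(sc, config.coverage, config.error_rate,
                              seed=config.seed + 1)
    write_genome(sc.reference, out / "reference.fasta", out / "reference.gff3")
    write_genome(sc.parasite, out / "parasite.fasta", out / "parasite.gff3")
    sc.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    reads.write_fastq(str(out / "reads"))
    manifest["stages"]["simulate"] = {
        "reference_len": len(sc.reference),
        "parasite_len": len(sc.parasite),
        "n_read_pairs": len(reads),
    }

    # 2. detect IR -----------------------------------------------------
    placements = map_read_set(reads, sc.parasite)
    cov = coverage_profile(placements)
    cands = find_inverted_candidates(sc.parasite.sequence,
                                     min_len=config.min_ir_len)
    ir_call = call_ir(
        cands, cov, lambda c: split_pair_evidence(placements, c),
        IRCallConfig(config.min_ir_len, config.min_pairs),
    )
    _write_json(out / "ir_call.json",
                ir_call.to_dict() if ir_call else None)
    if ir_call:
        bed = [
            f"parasite\t{ir_call.interval_a[0]}\t{ir_call.interval_a[1]}\tIRa",
            f"parasite\t{ir_call.interval_b[0]}\t{ir_call.interval_b[1]}\tIRb",
        ]
        (out / "ir.bed").write_text("\n".join(bed) + "\n")
    manifest["stages"]["detect_ir"] = {
        "called": ir_call is not None,
        "ir_len": ir_call.length if ir_call else 0,
        "mean_depth": round(float(cov.depth.mean()), 2),
    }

    # 3. partition -----------------------------------------------------
    qmap = partition_quadripartite(sc.parasite, ir_call)
    _write_json(out / "quadripartite.json", qmap.to_dict())
    manifest["stages"]["partition"] = qmap.to_dict()

    # 4. gene status ---------------------------------------------------
    searcher = TargetSearcher(sc.parasite, config.classify.seed_k)
    calls = {
        f.name: classify_gene(searcher, f, sc.reference, config.classify)
        for f in sc.reference.features
    }
    status = pd.DataFrame(
        {"parasite": {g: c.status for g, c in calls.items()}}
    )
    status.to_csv(out / "status_matrix.tsv", sep="\t")
    evidence = {
        g: {
            "status": c.status,
            "evidence": sorted(c.evidence),
            "identity": round(c.identity, 2),
            "covered_fraction": round(c.covered_fraction, 3),
        }
        for g, c in calls.items()
    }
    fragments = {}
    for g, c in calls.items():
        if c.status != "absent":
            continue
        v = verify_absence(g, sc.reference, reads, config.coverage,
                           status_call=c)
        fragments[g] = {
            "verdict": v.kind,
            "relative_depth": (round(v.relative_depth, 3)
                               if v.relative_depth else None),
            "span": list(v.span) if v.span else None,
        }
    _write_json(out / "gene_status.json",
                {"calls": evidence, "absence_verification": fragments})
    classified = dataclasses.replace(
        sc.parasite,
        features=[
            dataclasses.replace(f, status=calls[f.name.replace("_2", "")].status)
            for f in sc.parasite.features
        ],
    )
    summary = summarize_coding_capacity(classified)
    n_lost_protein = sum(
        1 for f in sc.reference.features
        if f.gene_type == "protein" and calls[f.name].status != "intact"
    )
    summary["protein_genes_lost_or_pseudogenized"] = n_lost_protein
    _write_json(out / "coding_capacity.json", summary)
    manifest["stages"]["gene_status"] = {
        "intact": summary["by_type"],
        "protein_losses": n_lost_protein,
        "fragments_found": sum(
            1 for v in fragments.values() if v["verdict"] == "fragment_found"
        ),
    }

    # 5. repeats -------------------------------------------------------
    if "repeats" in config.stages:
        _stage_repeats(config, sc, out, manifest)
    if "synteny" in config.stages:
        _stage_synteny(config, sc, qmap, out, manifest)
    if "traits" in config.stages:
        _stage_traits(config, out, manifest)

    # 8. report --------------------------------------------------------
    _write_json(out / "manifest.json", manifest)
    return manifest


def _stage_repeats(config, sc, out, manifest):
    hits = find_maximal_repeats(
        sc.parasite.sequence, config.repeat_min_len,
        config.repeat_max_mismatch, config.repeat_max_evalue,
    )
    pd.DataFrame(
        [
            {"class": h.cls, "start_a": h.start_a, "start_b": h.start_b,
             "length": h.length, "mismatches": h.mismatches,
             "e_value": h.e_value}
            for h in hits
        ]
    ).to_csv(out / "repeats.tsv", sep="\t", index=False)
    tandems = find_tandem_repeats(sc.parasite.sequence,
                                  config.tandem_min_total,
                                  config.tandem_unit_range)
    pd.DataFrame(
        [{"start": t.start, "total_len": t.total_len, "unit": t.unit,
          "copies": round(t.copies, 2)} for t in tandems]
    ).to_csv(out / "tandems.tsv", sep="\t", index=False)
    dens = repeat_density(hits, len(sc.parasite))
    dens["n_tandems"] = len(tandems)
    _write_json(out / "repeat_density.json", dens)
    manifest["stages"]["repeats"] = dens



def _stage_synteny(config, sc, qmap, out, manifest):
    collapsed = dataclasses.replace(collapse_ir(sc.parasite, qmap),
                                    id="parasite")
    intact = set(sc.truth.gene[sc.truth.status == "intact"])
    names = [f.name for f in sc.reference.features if f.name in intact]
    variants = []
    for i, (a, b) in enumerate((
        (names[10], names[20]), (names[40], names[55]),
    )):
        v, _ = degrade_plastome(
            sc.reference, DegradationScenario(inversions=[(a, b)]),
            seed=config.seed + 10 + i,
        )
        variants.append(dataclasses.replace(v, id=f"relative{i + 1}"))
    genomes = [sc.reference] + variants + [collapsed]
    lcbs = build_lcbs(genomes, min_block_len=config.min_block_len)
    rows = []
    for gid, blocks in lcbs.per_genome.items():
        for b, s, e, st in blocks:
            rows.append({"genome": gid, "block": b, "start": s, "end": e,
                         "strand": st})
    pd.DataFrame(rows).to_csv(out / "blocks.tsv", sep="\t", index=False)
    perms = lcbs.permutations()
    ids = [g.id for g in genomes]
    dmat = {
        a: {
            b: {
                "breakpoint": breakpoint_distance(perms[a], perms[b]),
                "reversal": reversal_distance(perms[a], perms[b]),
            }
            for b in ids
        }
        for a in ids
    }
    newick = "((reference:1,(relative1:1,relative2:1):1):1,parasite:2);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    res = count_tree_rearrangements(tree, perms)
    _write_json(out / "synteny.json", {
        "n_blocks": lcbs.n_blocks,
        "distances": dmat,
        "tree_total_reversals": res.total,
        "per_branch": res.per_branch,
        "heuristic": res.heuristic,
    })
    manifest["stages"]["synteny"] = {
        "n_blocks": lcbs.n_blocks, "tree_total": res.total,
    }



def _stage_traits(config, out, manifest):
    if config.tree_file:
        tr = dendropy.Tree.get(path=config.tree_file, schema="newick")
        tt = pd.read_csv(config.traits_file, sep="\t", index_col=0)
        trait_pairs = [tuple(tt.columns[:2])]
        tables = {tuple(tt.columns[:2]): tt}
    else:
        tr = random_tree(config.n_trait_taxa, config.seed + 100)
        rng = np.random.default_rng(config.seed + 101)
        R = np.array([[1.0, 0.0], [0.0, 1.0]])
        cont = simulate_traits(tr, R, seed=config.seed + 102)
        cont.columns = ["repeat_density", "n_rearrangements"]
        liab = simulate_traits(tr, R, seed=config.seed + 103)
        binary = (liab > liab.median()).astype(float)
        binary.columns = ["ir_presence", "heterotrophy"]
        tt = pd.concat([cont, binary], axis=1)
        trait_pairs = [
            ("n_rearrangements", "heterotrophy"),
            ("ir_presence", "n_rearrangements"),
            ("ir_presence", "repeat_density"),
            ("repeat_density", "heterotrophy"),
            ("repeat_density", "n_rearrangements"),
        ]
        tables = {p: tt[list(p)] for p in trait_pairs}
    tt.to_csv(out / "traits.tsv", sep="\t")
    lrt_out = {}
    for pair in trait_pairs:
        res = lrt_correlation(tr, tables[pair])
        lrt_out["__".join(pair)] = res.to_dict()
    _write_json(out / "trait_lrt.json", lrt_out)
    manifest["stages"]["traits"] = {
        k: round(v["p"], 4) for k, v in lrt_out.items()
    }
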