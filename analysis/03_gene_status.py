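#!/usr/bin/env python
"""Classify every reference gene in the degraded plastome and verify
absences against the read pool.

Writes the gene x taxon status matrix, per-gene evidence records, and
the coding-capacity summary under results/status/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from plastid_erosion.scenarios import build_parasite_genome, \
    parasite_read_set
from plastid_erosion.status import TargetSearcher, classify_gene, \
    verify_absence


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--coverage", type=float, default=60.0)
    ap.add_argument("--out", default="results/status")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    sc = build_parasite_genome(seed=args.seed)
    reads = parasite_read_set(sc, args.coverage, seed=args.seed + 1)
    searcher = TargetSearcher(sc.parasite)
    calls = {f.name: classify_gene(searcher, f, sc.reference)
             for f in sc.reference.features}

    truth = dict(zip(sc.truth.gene, sc.truth.status))
    agree = sum(calls[g].status == truth[g] for g in calls)
    matrix = pd.DataFrame({"parasite": {g: c.status
                                        for g, c in calls.items()}})
    matrix.to_csv(out / "status_matrix.tsv", sep="\t")
    evidence = {
        g: {"status": c.status, "evidence": sorted(c.evidence),
            "identity": round(c.identity, 2),
            "covered_fraction": round(c.covered_fraction, 3)}
        for g, c in calls.items()
    }
    fragments = {}
    for g, c in calls.items():
        if c.status != "absent":
            continue
        v = verify_absence(g, sc.reference, reads, args.coverage,
                           status_call=c)
        fragments[g] = {
            "verdict": v.kind,
            "relative_depth": (round(v.relative_depth, 3)
                               if v.relative_depth else None),
        }
    (out / "gene_status.json").write_text(json.dumps(
        {"calls": evidence, "absence_verification": fragments},
        indent=2, sort_keys=True) + "\n")

    by_type = {"protein": 0, "trna": 0, "rrna": 0}
    for f in sc.reference.features:
        if calls[f.name].status == "intact":
            by_type[f.gene_type] += 1
    n_frag = sum(1 for v in fragments.values()
                 if v["verdict"] == "fragment_found")
    print(f"classified {len(calls)} genes; {agree}/{len(calls)} match "
          f"planted truth")
    print(f"intact: {by_type['protein']} protein / {by_type['trna']} tRNA "
          f"/ {by_type['rrna']} rRNA = {sum(by_type.values())} unique genes")
    print(f"protein genes lost or pseudogenized: "
          f"{82 - by_type['protein']} of 82")
    print(f"absent genes with low-depth insert fragments: {n_frag} "
          f"(all relative depth < 1)")


if __name__ == "__main__":
    main()
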