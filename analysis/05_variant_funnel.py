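#!/usr/bin/env python
"""Trio variant funnel and candidate prioritisation.

Filters the sequenced family's variants (protein-changing, private against
the local then global control cohorts), classifies inheritance modes from
the two parent-offspring trios, and ranks the surviving candidates by
overlap with the linkage regions and shared-autozygosity segments from the
previous steps.  Writes results/candidates.tsv.
"""

import argparse
import json

from comphet.io_formats import read_vcf
from comphet.linkage import LinkedRegion
from comphet.pedigree import read_fam
from comphet.variant_filter import ControlCohort, prioritize, run_funnel


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/flock")
    ap.add_argument("--regions", default="results/linkage/regions.bed")
    ap.add_argument("--shared-roh", default="results/roh/compound_het_shared.bed")
    ap.add_argument("--out", default="results/candidates.tsv")
    args = ap.parse_args()

    variants = read_vcf(f"{args.data}/family.vcf")
    ped = read_fam(f"{args.data}/flock.fam")
    local = ControlCohort.from_table(f"{args.data}/local_counts.tsv", "local")
    global_ = ControlCohort.from_table(f"{args.data}/global_counts.tsv", "global")
    samples = sorted({s for v in variants for s in v.genotypes})
    cases = [c for c in (i.id for i in ped if i.phenotype == "affected")
             if c in samples]
    trios = [(c, ped[c].sire_id, ped[c].dam_id) for c in cases]

    regions = []
    for line in open(args.regions):
        f = line.split("\t")
        regions.append(LinkedRegion(f[0], int(f[1]), int(f[2]), 0, 0.0,
                                    float(f[4])))
    shared = []
    try:
        for line in open(args.shared_roh):
            f = line.split("\t")
            shared.append({"chrom": f[0], "start": int(f[1]),
                           "end": int(f[2]), "n_snps": 0})
    except FileNotFoundError:
        shared = []

    res = run_funnel(variants, trios, cases, local, global_)
    print("funnel:", json.dumps(res["log"]))
    report = prioritize(res["final_calls"], regions, shared)
    with open(args.out, "w") as fh:
        fh.write("rank\tgene\tmode\tvariants\tin_linked_region\t"
                 "in_shared_roh\tsupport_lod\trationale\n")
        for rank, c in enumerate(report.candidates, 1):
            names = ",".join(f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}"
                             for v in c.call.variants)
            fh.write(f"{rank}\t{c.call.gene_id}\t{c.call.mode}\t{names}\t"
                     f"{c.in_linked_region}\t{c.in_shared_roh}\t"
                     f"{c.support_lod:.2f}\t{c.rationale}\n")
    top = report.candidates[0]
    print(f"top candidate: {top.call.gene_id} ({top.call.mode}); "
          f"{top.rationale}")
    print(f"written {args.out}")


if __name__ == "__main__":
    main()
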