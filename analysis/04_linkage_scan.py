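#!/usr/bin/env python
"""Nonparametric allele-sharing linkage scan of the simulated flock.

Computes the pairs statistic per marker, standardises it against a
gene-drop Monte-Carlo null, merges positive-score markers into candidate
regions, and writes the scan table and region BED under results/linkage/.
"""

import argparse
import os

from comphet.io_formats import read_genotypes
from comphet.linkage import LinkageParams, scan_and_merge
from comphet.pedigree import read_fam


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/flock")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=1000)
    ap.add_argument("--out", default="results/linkage")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    gm = read_genotypes(f"{args.data}/flock.ped", f"{args.data}/flock.map")
    ped = read_fam(f"{args.data}/flock.fam")
    affected = [i.id for i in ped if i.phenotype == "affected"
                and i.id in gm.sample_ids]
    scan, regions = scan_and_merge(gm, ped, affected,
                                   LinkageParams(n_reps=args.reps,
                                                 seed=args.seed))
    scan.to_csv(os.path.join(args.out, "scan.tsv"), sep="\t", index=False)
    with open(os.path.join(args.out, "regions.bed"), "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"n={r.n_markers};maxZ={r.max_Z:.2f}\t"
                     f"{r.max_LOD:.3f}\n")
    best = max(regions, key=lambda r: r.max_LOD)
    print(f"{len(scan)} markers scanned "
          f"({int(scan['Z'].notna().sum())} informative), "
          f"{len(regions)} positive-score regions")
    print(f"strongest region: chr{best.chrom}:{best.start}-{best.end} "
          f"(peak LOD {best.max_LOD:.2f}, {best.n_markers} markers)")


if __name__ == "__main__":
    main()
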