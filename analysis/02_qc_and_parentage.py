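#!/usr/bin/env python
"""Array QC and pedigree verification on the simulated flock.

Reads results/flock/, reports per-sample call rates, prunes markers with
>10% missingness, verifies the declared sire by opposing homozygotes for
every genotyped lamb, and ranks candidate dams for each affected lamb.
Writes results/qc_parentage.json.
"""

import argparse
import json

from comphet.genotype_qc import prune_markers_by_missingness, sample_call_rates
from comphet.io_formats import read_genotypes
from comphet.pedigree import assign_maternity, read_fam, verify_parentage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/flock")
    ap.add_argument("--out", default="results/qc_parentage.json")
    args = ap.parse_args()

    gm = read_genotypes(f"{args.data}/flock.ped", f"{args.data}/flock.map")
    ped = read_fam(f"{args.data}/flock.fam")
    rates = sample_call_rates(gm)
    pruned = prune_markers_by_missingness(gm)
    print(f"call rates: min {rates.rates.min():.3f}; "
          f"{len(rates.flagged)} sample(s) below 0.90")
    print(f"markers: {gm.n_markers} -> {pruned.n_markers} after pruning")

    lambs = [i.id for i in ped if i.sire_id == "RAM" and i.id in gm.sample_ids]
    parentage = {l: verify_parentage(pruned, l, "RAM").verdict for l in lambs}
    print(f"sire confirmed for "
          f"{sum(v == 'confirmed' for v in parentage.values())}/{len(lambs)} lambs")

    dams = [i.id for i in ped
            if i.sex == "female" and i.id in gm.sample_ids
            and i.sire_id != "RAM"]  # candidate dams are ewes, not lambs
    maternity = {}
    for l in lambs:
        if ped[l].phenotype != "affected":
            continue
        ranked = assign_maternity(pruned, l, dams)
        maternity[l] = [(v.parent_id, v.verdict,
                         v.n_opposing_homozygotes) for v in ranked[:3]]
        print(f"{l}: best dam {ranked[0].parent_id} ({ranked[0].verdict})")

    with open(args.out, "w") as fh:
        json.dump({"call_rates": dict(zip(rates.sample_ids,
                                          rates.rates.tolist())),
                   "markers_after_pruning": pruned.n_markers,
                   "sire_verdicts": parentage,
                   "maternity_top3": maternity}, fh, indent=2)
    print(f"written {args.out}")


if __name__ == "__main__":
    main()
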