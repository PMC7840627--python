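# comphet — trio-based discovery of compound-heterozygous disease variants

`comphet` implements the disease-gene discovery workflow used in livestock
family studies where a recessive-appearing disorder turns out to be caused
by **compound heterozygosity**: two different loss-of-function alleles of
one gene, one inherited from each parent. The scenario it is built around
is a half-sib flock — one sire over many ewes, the ewes themselves
daughters of a single (unsampled) grandsire — with a handful of affected
lambs. In that design an autozygosity scan comes back empty (the affected
are *not* homozygous for a shared haplotype), and the resolution comes
from combining nonparametric linkage with trio-based variant filtering.

The pipeline covers, end to end:

* **SNP-array QC** — per-sample call rates, pruning of markers with >10%
  missing calls;
* **parentage verification** — opposing-homozygote counts confirm the
  sire and assign the dams;
* **autozygosity mapping** — rule-based runs-of-homozygosity per animal
  and allele-matched shared segments across cases;
* **nonparametric linkage** — a singlepoint affected-pairs
  allele-sharing statistic S, standardised against a gene-drop
  Monte-Carlo null into Z and LOD = sign(Z)·Z²/(2 ln 10), with positive-
  score markers merged into candidate regions. Pairs whose dams share an
  ungenotyped sire get an exact grandsire-aware conditional expectation
  that also captures maternal-path IBD;
* **variant funnel** — protein-changing effects only, private against a
  local (60-genome) and a global (453-genome) control cohort, trio
  phasing, classification into recessive-homozygous vs compound-
  heterozygous (requiring *trans* configuration), prioritisation by
  overlap with linkage regions and shared autozygosity;
* **consequence prediction** — isoform-aware coordinate mapping with
  intronic offsets, canonical-splice-site disruption with nearest-AG
  cryptic-acceptor rescue, frameshift translation, and HGVS c./p.
  nomenclature (e.g. `c.210-2A>G`, `p.Leu71TrpfsTer3`).

Everything runs on a synthetic-flock generator (`comphet.synthetic_data`)
that encodes the study design with full ground truth (founder-haplotype
labels for every transmission), so each stage is testable without any
data download. See `docs/methods.md` for the models and parameter
choices.

## Worked example

The numbered scripts under `analysis/` replay the study narrative and
write their tables under `results/`:

```bash
python analysis/01_simulate_flock.py --seed 1
python analysis/02_qc_and_parentage.py
python analysis/03_autozygosity.py --seed 1
python analysis/04_linkage_scan.py --seed 1
python analysis/05_variant_funnel.py
python analysis/06_consequences.py
```

which prints (seed 1):

```
flock written to results/flock: 5 affected lambs, 14 array-genotyped animals, 5000 markers; ...
call rates: min 0.978; 0 sample(s) below 0.90
markers: 5000 -> 4833 after pruning
sire confirmed for 8/8 lambs
L06: best dam EW01 (confirmed)
...
compound_het: per-case ROH {'L06': 53, ...}; 0 shared allele-matched interval(s)
no shared homozygous interval in the study flock: a simple autozygous recessive locus is not supported
recessive_control: ...; 1 shared allele-matched interval(s)
5000 markers scanned (3981 informative), 875 positive-score regions
funnel: {"input": 34, "protein_changing": 26, "private_vs_local": 7, "mode_fitting_local": 4, "private_vs_global": 3}
top candidate: geneC (compound_het); maps to a linked region
```

Reading it: all 14 genotyped animals pass the 90% call-rate bar and the
declared pedigree is confirmed; the affected lambs share **no**
allele-matched homozygous segment (so a simple autozygous recessive model
fails, while the recessive positive-control flock recovers its causal
interval); the variant funnel narrows 34 family variants to a handful of
mode-compatible private candidates; and the planted compound-het pair in
`geneC` ranks first because it is the candidate supported by a linkage
region. The consequence step names the two engineered toy-gene variants:
the acceptor-loss variant `c.210-2A>G` activates a cryptic AG 10 bases
into the exon, frameshifting into `p.Leu71TrpfsTer3` (a 72-residue
protein, >90% truncated), and a single exonic C>T reads as nonsense
`p.Gln396Ter` on the short isoform but missense `p.Leu396Phe` on the
insert-bearing long isoform.

The same stages are available as a CLI
(`comphet qc|parentage|roh|linkage|filter|consequence|simulate|discover`),
e.g. a full run from files:

```bash
comphet simulate flock --seed 1 --out data/
comphet discover --config pipeline.yaml --out out/
```

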