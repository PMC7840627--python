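# Methods

`comphet` re-creates, as a tested pipeline over synthetic data, the
family-study workflow that identifies a compound-heterozygous
loss-of-function cause for a recessive-appearing disease in a livestock
flock: array QC and parentage verification, autozygosity mapping,
nonparametric allele-sharing linkage, a trio-based variant funnel, and
isoform-aware consequence prediction.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The study design the generator emulates

The synthetic flock (`synthetic_data.simulate_flock`) encodes a classic
half-sib design. One ungenotyped grandsire carries variant A (a splice
acceptor variant) and sires the whole ewe cohort, so each of the 52 ewes
inherits A with probability 1/2. The single sire of all lambs carries
variant B (an exonic variant in the same gene). A lamb is affected iff it
carries both A (necessarily maternal) and B (necessarily paternal) —
compound heterozygosity with full penetrance. Default counts: 52 ewes, 1
sire, 18 lambs of which 5 are affected (`n_affected=5`, enforced by
redrawing the lamb generation with distinct dams for the affected;
`n_affected=None` yields the natural binomial draw). The array-genotyped
subset mirrors the study: the sire, the five dams of affected lambs, the
five affected and three unaffected lambs (14 animals). The sequenced
subset is the sire, two dams and two affected lambs — two complete trios.

A `recessive` mode makes the sire a son of the grandsire and plants a
single variant, so affected lambs are autozygous for a grandsire
haplotype around the locus — the positive control for autozygosity
mapping.

Markers (default 5 000, scalable) are biallelic with allele frequencies
uniform on [0.1, 0.9], missingness 2%, genotyping error 0 by default.
There is genetic linkage but no linkage disequilibrium: founder
haplotypes carry independent alleles, and meioses are crossover Poisson
processes at 1 cM/Mb (Haldane, no interference) on 26 chromosomes of
100 Mb. Every transmission is recorded as founder-haplotype labels
(`FlockTruth`), the exact IBD oracle used by the tests; emitted genotypes
are audited against the labels at generation time. What the generator
does **not** emulate: linkage disequilibrium, allele-frequency spectra,
genotype-calling artefacts beyond uniform error/missingness, and
population structure in the control cohorts (these are emitted as
site-level carrier counts: 60 local and 453 global genomes that carry
neither causal variant). Passing tests therefore demonstrate the
pipeline's logic and calibration under Mendelian transmission, not
robustness to real-array artefacts.

## Parentage

Single-parent checks count opposing homozygotes (child and candidate
homozygous for different alleles), the only single-parent Mendelian
impossibility. Verdicts: confirmed below an error rate of 0.001,
excluded above 0.01, ambiguous between — conventional SNP-array
thresholds, not estimated from data, and overridable. Maternity
assignment ranks candidates by that rate, flags ties, and never confirms
more than one dam. Full trio-inconsistency patterns (child het, both
parents hom-ref) are instead surfaced by the variant funnel's phasing.

## Autozygosity

ROH detection is a rule-based consecutive-run scan: a run starts and ends
at homozygous calls and tolerates at most `max_het` heterozygous and
`max_miss` missing calls; reported when it has ≥ `min_snps` markers and
spans ≥ `min_length` bases. Defaults (40 SNPs, 2 Mb, 1 het, 2 missing)
are calibrated to ~50k markers on a ~2.6 Gb genome; `ROHParams.scaled_to`
rescales the SNP-count thresholds proportionally for sparser panels
(e.g. 16 SNPs at 20k markers). Shared autozygosity intersects the cases'
segments — bridging micro-gaps of ≤3 markers left where a run's
tolerance counters overflowed — and then enforces marker-wise agreement:
every non-missing call homozygous for the *same* allele in all cases.
Intersection pieces keep the `min_snps` support requirement but not the
physical-length floor, which belongs to single-animal segments. On
20k-marker flocks this recovers the planted recessive interval in ≥95%
of runs while compound-het flocks essentially never yield a shared
segment.

## Linkage

The statistic is a singlepoint affected-pairs score. For each pair, the
expected number of alleles shared identical-by-descent through the
pedigree paths the data can see, conditional on the single-marker
genotypes, normalised by 2 (a fully shared full-sib pair contributes 1.0).
Three pair types:

* full sibs — exact enumeration over the four parental transmissions;
* plain half sibs — enumeration over the shared parent's transmissions,
  the other parent marginalised;
* half sibs whose dams are half-sibs through a shared **ungenotyped**
  sire (the study design) — a grandsire-aware enumeration that also
  estimates maternal-path IBD, marginalising the grandsire's two alleles
  and every dam/lamb transmission exactly, with founder alleles at the
  marker's estimated frequency. Prior sharing for such a pair is
  1/2 paternal + 1/8 maternal. This term is what gives the scan its
  power in the half-sib design: the affected share both a sire haplotype
  and a grandsire haplotype at the causal locus.

A pair is *informative* at a marker when its posterior moves off its
prior by more than 0.01 for the exactly-enumerated types, or 0.05 (about
an eighth of the null standard deviation) for the frequency-weighted
grandsire type; below that the score's sign is Monte-Carlo noise. A
marker with no informative pair is undefined.

Allele frequencies are estimated from genotyped founders only (the sire
and the dams; never affected lambs) and clamped away from 0/1. Each
marker is folded to its minor-allele labelling before scoring, which
makes the scan exactly invariant to allele relabelling.

The null is gene drop: founder alleles drawn at the folded frequency and
transmitted through the pedigree with no linkage to phenotype;
individuals ungenotyped in the data are masked in the drops, and
replicates accumulate until 1 000 *informative* ones per unique
frequency (the observed scan conditions on informativeness, so the null
must too). Because the statistic's null is skewed and discrete, the
standardised score is the normal quantile of the empirical mid-p against
the null sample, not a moment standardisation — this is what makes
P(Z>0) ≈ 0.5 and P(Z>1.96) ≈ 0.025 under permuted phenotypes. The
empirical null mean/sd are still reported per marker, and
LOD = sign(Z)·Z²/(2 ln 10).

Regions are maximal runs of consecutive Z>0 markers, bridging up to
`gap_markers` (default 10) undefined markers — with a singlepoint
statistic a large fraction of markers is uninformative and breaking on
each would shatter true regions. A region's genomic span extends beyond
its outermost positive markers to the midpoint toward the first
contradicting (Z≤0) marker, since uninformative markers carry no
boundary evidence. Multipoint likelihoods (Lander–Green) are out of
scope by design; region calling consumes only the sign of the score.

## Variant funnel

Effect classes counted as protein-changing: missense, nonsense,
frameshift, splice acceptor/donor (canonical ±2 nt), start/stop lost,
in-frame indel, other-protein-changing. "Private" means a site-level
alternate-allele carrier count of 0 in a control cohort
(`max_control_carriers` relaxes this). Order of stages mirrors the study:
protein-changing → private against the 60-genome local cohort →
inheritance-mode classification from the trios → private against the
453-genome global cohort, with per-stage variant counts logged
(monotone by construction).

Trio phasing of a heterozygous child's alternate allele: paternal if only
the sire carries it, maternal if only the dam, ambiguous if both (or a
parent is untyped), and a Mendelian inconsistency if neither.
`recessive_hom` requires all cases homozygous-alt with all genotyped
parents het; `compound_het` requires two variants of one gene, every case
het for both, opposite parental origins in every phasable case, and no
origin conflict — a pair travelling on the same parental haplotype is cis
and rejected. Cases without a complete trio contribute genotype
compatibility but no phase.

Prioritisation: candidates overlapping a linkage region (or, for
recessive candidates, a shared-autozygosity segment) rank above the rest;
ties break on the supporting region's peak LOD. When the autozygosity
analysis was performed, a recessive candidate outside every shared
segment is additionally demoted: a true recessive locus must be
autozygous in the cases. Exclusion rationales are recorded verbatim in
the report. Obligate-carrier deduction finds the minimal set of common
ancestors (typically the phantom grandsire) whose carrier status explains
all observed carrier dams; with disjoint carrier ancestries it reports
that a single-ancestor explanation is impossible (germline mosaicism or
multiple origins).

## Consequence engine

Coordinates are 0-based half-open internally; HGVS output is 1-based,
with intronic offsets (c.N±k), 3-letter amino acids and "Ter" ("*"
accepted on input). Only the canonical GT/AG dinucleotides at intronic
±1/±2 are splice-disrupting; ±3..8 is annotated `splice_region` and not
protein-changing. Acceptor loss moves the exon's 5′ boundary to just
after the nearest downstream AG within a 50-base exonic window (no
splice-strength scoring — the nearest-AG rule is the validated case);
without an AG the exon is skipped, and if skipping removes the CDS start
no rescue is modelled. Donor loss mirrors this with an upstream GT scan
and is flagged lower-confidence. Frameshift naming: first divergent
residue, new residue, `fsTer` + stop index in the new frame counting the
divergent residue as 1; a mutant without a stop gets `Ter?`. Truncation
is reported as a fraction of the reference protein; nonsense-mediated
decay is never predicted. Each transcript covering a variant gets its own
call, because alternative splicing can re-split a junction codon — the
engineered two-isoform toy gene reproduces exactly this: one genomic C>T
is p.Gln396Ter on the short isoform and p.Leu396Phe on the
insert-bearing long one. All toy-gene structural claims (10-base
cryptic-acceptor deletion, 72-residue truncated protein, >90% loss) are
asserted at construction time, and every toy has a reverse-strand mirror
for strand-symmetry testing.

## Problem sizes and tolerances

End-to-end recovery experiments use 100 flocks of 5 000 markers;
autozygosity discrimination uses 100 recessive + 100 compound-het flocks
of 20 000 markers; null calibration uses 20 flocks of 2 000 markers with
phenotype labels permuted among the genotyped lambs, judged within 3
standard errors over replicates. These sizes give stable Monte-Carlo
estimates while keeping a full run on one CPU in minutes. The gene-drop
null uses 1 000 informative replicates per unique founder frequency;
frequencies from ~6 genotyped founders take few unique values, so nulls
are shared across markers and the scan is effectively linear in marker
count.

## Known limitations

* The linkage scan is singlepoint; it trades the power of multipoint NPL
  for auditability, and its region count is not comparable to multipoint
  region counts.
* The grandsire-aware pair model covers the one extended relationship
  the design needs; deeper or different hidden coancestry (e.g. shared
  dams' dams) is not modelled and simply contributes no estimated IBD.
* Privacy filtering is site-level; it cannot distinguish a recurrent
  mutation from shared ancestry in controls.
* The cryptic-splice model knows nothing about splice-site strength;
  it implements the nearest-AG/GT rule only.
* The fixed verdict/ROH thresholds are conventions, chosen a priori and
  exposed as configuration, not values learned from data.
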