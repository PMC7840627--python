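"""The whole-genome-sequence candidate funnel.

Stages, each a subset of its input, with counts logged:

1. protein-changing effect classes only;
2. *private* variants — every case carries the alternate allele, no control
   sample (local cohort, then global cohort) carries it.  "Private" means a
   carrier count of 0 at site level; ``max_control_carriers`` relaxes this
   for sensitivity analysis;
3. inheritance-mode classification from parent-offspring trios:
   ``recessive_hom`` (all cases hom-alt, all genotyped parents het) or
   ``compound_het`` (two variants of one gene, every case het for both,
   with *opposite* parental origins in every phasable case — a pair whose
   members travel on the same parental haplotype is cis and is rejected);
4. prioritisation by overlap with linkage regions (and, for recessive
   candidates, shared autozygosity segments), with an explicit exclusion
   rationale for candidates supported by neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from comphet.io_formats import VariantRecord, HOM_REF, HET, HOM_ALT, MISSING
from comphet.pedigree import Pedigree

PROTEIN_CHANGING = {
    "missense", "nonsense", "frameshift", "splice_acceptor", "splice_donor",
    "start_lost", "stop_lost", "inframe_indel", "other_protein_changing",
}


# ---------------------------------------------------------------------------
# Control cohorts
# ---------------------------------------------------------------------------


class ControlCohort:
    """Site-level alternate-allele carrier counts for a control cohort.

    Built either from explicit per-variant counts or from control sample
    genotypes.  A variant absent from the table is treated as unobserved
    (0 carriers) and flagged.
    """

    def __init__(self, carrier_counts: dict[tuple, int] | None = None,
                 n_samples: int | None = None, name: str = "controls"):
        self.counts = dict(carrier_counts or {})
        self.n_samples = n_samples
        self.name = name

    @classmethod
    def from_variants(cls, variants: list[VariantRecord], name: str = "controls"):
        counts = {v.key: len(v.carriers()) for v in variants}
        n = len({s for v in variants for s in v.genotypes})
        return cls(counts, n_samples=n, name=name)

    @classmethod
    def from_table(cls, path: str, name: str = "controls"):
        """Read a site-level carrier-count TSV (chrom, pos, ref, alt, carriers)."""
        counts: dict[tuple, int] = {}
        n_samples = None
        with open(path) as fh:
            header = fh.readline().split()
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.split()
                if not f:
                    continue
                key = (f[idx["chrom"]], int(f[idx["pos"]]) - 1,
                       f[idx["ref"]], f[idx["alt"]])
                counts[key] = int(f[idx["carriers"]])
                if "n_samples" in idx:
                    n_samples = int(f[idx["n_samples"]])
        return cls(counts, n_samples=n_samples, name=name)

    def carrier_count(self, v: VariantRecord) -> tuple[int, bool]:
        """(carriers, observed_in_table) for a variant."""
        if v.key in self.counts:
            return self.counts[v.key], True
        return 0, False


# ---------------------------------------------------------------------------
# Effect and privacy filters
# ---------------------------------------------------------------------------


def filter_protein_changing(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep protein-changing records, preserving input order.

    Records lacking an effect class are rejected loudly: they must be routed
    through the consequence engine (or carry a VCF EFFECT annotation) first.
    """
    missing = [v for v in variants if v.effect_class is None]
    if missing:
        v = missing[0]
        raise ValueError(
            f"{len(missing)} unannotated record(s), first at {v.chrom}:{v.pos1}; "
            "annotate effects before filtering")
    return [v for v in variants if v.effect_class in PROTEIN_CHANGING]


def filter_private(variants: list[VariantRecord], case_ids: list[str],
                   control: ControlCohort,
                   max_control_carriers: int = 0) -> list[VariantRecord]:
    """Variants carried by every case and by <= k control samples (default 0)."""
    out = []
    for v in variants:
        if not all(v.genotypes.get(c, MISSING) in (HET, HOM_ALT) for c in case_ids):
            continue
        n, observed = v.carrier_count_cache = control.carrier_count(v)
        if n <= max_control_carriers:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Trio phasing and inheritance-mode classification
# ---------------------------------------------------------------------------


def phase_by_trio(variant: VariantRecord, trio: tuple[str, str, str]) -> str:
    """Parental origin of a heterozygous child's alternate allele.

    Returns ``paternal``, ``maternal``, ``ambiguous`` (both parents carry
    it), ``mendelian_error`` (neither does), or ``not_applicable`` when the
    child is not heterozygous.
    """
    child, sire, dam = trio
    c = variant.genotypes.get(child, MISSING)
    if c != HET:
        return "not_applicable"
    s = variant.genotypes.get(sire, MISSING)
    d = variant.genotypes.get(dam, MISSING)
    s_carries = s in (HET, HOM_ALT)
    d_carries = d in (HET, HOM_ALT)
    if s == MISSING or d == MISSING:
        return "ambiguous"
    if s_carries and not d_carries:
        return "paternal"
    if d_carries and not s_carries:
        return "maternal"
    if s_carries and d_carries:
        return "ambiguous"
    return "mendelian_error"


@dataclass
class InheritanceCall:
    variants: list[VariantRecord]
    mode: str  # recessive_hom / compound_het / incompatible
    gene_id: str | None = None
    phase_evidence: dict = field(default_factory=dict)
    control_carrier_counts: tuple[int, int] | None = None
    mendelian_inconsistency: bool = False

    @property
    def positions(self) -> list[tuple[str, int]]:
        return [(v.chrom, v.pos) for v in self.variants]


def _is_recessive_hom(v: VariantRecord, trios, cases) -> tuple[bool, bool]:
    """(fits recessive_hom, saw mendelian error)."""
    if not all(v.genotypes.get(c, MISSING) == HOM_ALT for c in cases):
        return False, False
    parents = {p for t in trios for p in t[1:]}
    ok = all(v.genotypes.get(p, MISSING) == HET for p in parents)
    return ok, False


def classify_inheritance(variants: list[VariantRecord],
                         trios: list[tuple[str, str, str]],
                         cases: list[str]) -> list[InheritanceCall]:
    """Classify candidates as recessive_hom, compound_het or incompatible.

    Cases without a complete trio contribute genotype compatibility (het
    for both pair members) but no phase.  A compound-het call requires
    opposite parental origins in every phasable case and consistent origins
    across cases.
    """
    if not trios:
        raise ValueError("classification requires >= 1 complete trio")
    trio_of = {t[0]: t for t in trios}
    calls: list[InheritanceCall] = []
    claimed: set[tuple] = set()

    # single-variant recessive homozygous
    for v in variants:
        fits, _ = _is_recessive_hom(v, trios, cases)
        if fits:
            calls.append(InheritanceCall([v], "recessive_hom", gene_id=v.gene_id))
            claimed.add(v.key)

    # compound-het pairs within a gene
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.gene_id is not None:
            by_gene.setdefault(v.gene_id, []).append(v)
    for gene, vs in by_gene.items():
        for va, vb in combinations(vs, 2):
            if not all(va.genotypes.get(c, MISSING) == HET
                       and vb.genotypes.get(c, MISSING) == HET for c in cases):
                continue
            evidence = {}
            ok = True
            mend = False
            for c in cases:
                if c not in trio_of:
                    continue
                pa = phase_by_trio(va, trio_of[c])
                pb = phase_by_trio(vb, trio_of[c])
                evidence[c] = (pa, pb)
                if "mendelian_error" in (pa, pb):
                    mend = True
                    ok = False
                elif pa in ("paternal", "maternal") and pb in ("paternal", "maternal"):
                    if pa == pb:  # cis: same parental haplotype
                        ok = False
            if ok:
                calls.append(InheritanceCall(
                    [va, vb], "compound_het", gene_id=gene, phase_evidence=evidence))
                claimed.update((va.key, vb.key))

    # everything else is incompatible with the two recessive models
    for v in variants:
        if v.key not in claimed:
            mend = any(
                phase_by_trio(v, trio_of[c]) == "mendelian_error"
                for c in cases if c in trio_of)
            calls.append(InheritanceCall([v], "incompatible", gene_id=v.gene_id,
                                         mendelian_inconsistency=mend))
    return calls


# ---------------------------------------------------------------------------
# Segregation census over the full flock
# ---------------------------------------------------------------------------

CENSUS_CLASSES = ("WT/WT", "hetA_only", "hetB_only", "hetA+hetB", "other", "untyped")


def segregation_census(var_a: VariantRecord, var_b: VariantRecord,
                       sample_ids: list[str]) -> dict:
    """Two-variant genotype-class counts over a full flock.

    Variant A is conventionally the maternal-line variant, B the paternal.
    Samples missing either genotype land in ``untyped`` — never dropped.
    Returns class counts, per-class sample lists and the double carriers.
    """
    counts = {k: 0 for k in CENSUS_CLASSES}
    members: dict[str, list[str]] = {k: [] for k in CENSUS_CLASSES}
    for s in sample_ids:
        a = var_a.genotypes.get(s, MISSING)
        b = var_b.genotypes.get(s, MISSING)
        if a == MISSING or b == MISSING:
            k = "untyped"
        elif a == HET and b == HET:
            k = "hetA+hetB"
        elif a == HET and b == HOM_REF:
            k = "hetA_only"
        elif a == HOM_REF and b == HET:
            k = "hetB_only"
        elif a == HOM_REF and b == HOM_REF:
            k = "WT/WT"
        else:
            k = "other"
        counts[k] += 1
        members[k].append(s)
    return {"counts": counts, "members": members,
            "double_carriers": members["hetA+hetB"]}


# ---------------------------------------------------------------------------
# Obligate-carrier deduction for ungenotyped ancestors
# ---------------------------------------------------------------------------


def deduce_ancestor_carrier(ped: Pedigree, variant: VariantRecord,
                            carriers: list[str]) -> dict:
    """Minimal single-ancestor explanation of the observed carriers.

    If one individual (typically a phantom) is an ancestor of every carrier,
    a single mutation in that ancestor explains all carriers under
    Mendelian transmission; lacking a genotype, the ancestor is an obligate
    carrier *or* germline mosaic.  Disjoint carrier ancestries yield no
    single-ancestor explanation.
    """
    if not carriers:
        return {"explanation": "none", "ancestors": []}
    common: set[str] | None = None
    for c in carriers:
        anc = ped.ancestors(c)
        common = anc if common is None else (common & anc)
    common = common or set()
    if not common:
        return {"explanation": "no_single_ancestor",
                "ancestors": [],
                "statement": "carriers have disjoint ancestry: germline mosaic "
                             "or multiple mutation origins required"}
    # minimal = most recent common ancestors (no descendant also in the set)
    minimal = [a for a in common
               if not any(a in ped.ancestors(b) for b in common if b != a and b in ped)]
    minimal = sorted(minimal)
    return {"explanation": "single_ancestor",
            "ancestors": minimal,
            "statement": "; ".join(
                f"{a} is an obligate carrier or germline mosaic for "
                f"{variant.chrom}:{variant.pos1}{variant.ref}>{variant.alt}"
                for a in minimal)}


# ---------------------------------------------------------------------------
# Prioritisation
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    call: InheritanceCall
    in_linked_region: bool = False
    in_shared_roh: bool = False
    support_lod: float = 0.0
    rationale: str = ""


@dataclass
class CandidateReport:
    candidates: list[Candidate]
    no_regions_supplied: bool = False

    def ranked_genes(self) -> list[str | None]:
        return [c.call.gene_id for c in self.candidates]


def prioritize(calls: list[InheritanceCall], linked_regions,
               shared_roh) -> CandidateReport:
    """Rank candidates by positional support from linkage / shared ROH.

    Compound-het and recessive candidates overlapping a linked region (or,
    for recessive mode, a shared autozygosity segment) rank above those
    that overlap none; ties break on the supporting region's peak LOD.
    When an autozygosity analysis was performed (``shared_roh`` is a list,
    possibly empty), a recessive candidate lying outside every shared
    segment is demoted below equally-supported alternatives: a true
    recessive locus must be autozygous in the cases.  With no regions
    supplied at all the ordering falls back to inheritance-mode evidence
    alone and the report is flagged.
    """
    roh_performed = shared_roh is not None
    linked_regions = list(linked_regions or [])
    shared_roh = list(shared_roh or [])
    no_regions = not linked_regions and not shared_roh and not roh_performed
    cands: list[Candidate] = []
    for call in calls:
        if call.mode == "incompatible":
            continue
        in_link = False
        lod = 0.0
        for (chrom, pos) in call.positions:
            for r in linked_regions:
                if r.contains(chrom, pos):
                    in_link = True
                    lod = max(lod, r.max_LOD)
        in_roh = any(
            iv["chrom"] == chrom and iv["start"] <= pos < iv["end"]
            for (chrom, pos) in call.positions for iv in shared_roh)
        supported = in_link or (call.mode == "recessive_hom" and in_roh)
        if no_regions:
            rationale = "no linkage/ROH regions supplied; ranked on inheritance evidence alone"
        elif supported:
            rationale = "maps to a linked region" if in_link else \
                "lies in a shared homozygosity segment"
        else:
            rationale = ("neither located in a linked genome region nor in a "
                         "shared homozygosity segment: less likely candidate")
        cands.append(Candidate(call, in_link, in_roh, lod, rationale))

    def sort_key(c: Candidate):
        supported = (c.in_linked_region
                     or (c.call.mode == "recessive_hom" and c.in_shared_roh))
        no_autozygosity = int(roh_performed
                              and c.call.mode == "recessive_hom"
                              and not c.in_shared_roh)
        return (1 if no_regions or not supported else 0,
                no_autozygosity, -c.support_lod)

    cands.sort(key=sort_key)
    return CandidateReport(cands, no_regions_supplied=no_regions)


# ---------------------------------------------------------------------------
# Funnel driver
# ---------------------------------------------------------------------------


def run_funnel(variants: list[VariantRecord], trios, cases: list[str],
               local: ControlCohort, global_: ControlCohort,
               max_control_carriers: int = 0) -> dict:
    """Run effect -> local privacy -> inheritance -> global privacy.

    Mirrors the study order: candidates are classified after the local-cohort
    filter, then the surviving candidate *variants* are screened against the
    global cohort.  Stage counts (numbers of variants) are logged; the funnel
    is monotone by construction.
    """
    log = {"input": len(variants)}
    prot = filter_protein_changing(variants)
    log["protein_changing"] = len(prot)
    private_local = filter_private(prot, cases, local, max_control_carriers)
    log["private_vs_local"] = len(private_local)
    calls = classify_inheritance(private_local, trios, cases)
    fitting = [c for c in calls if c.mode in ("recessive_hom", "compound_het")]
    stage1_vars = {v.key: v for c in fitting for v in c.variants}
    log["mode_fitting_local"] = len(stage1_vars)
    survivors = filter_private(list(stage1_vars.values()), cases, global_,
                               max_control_carriers)
    log["private_vs_global"] = len(survivors)
    final_calls = classify_inheritance(survivors, trios, cases)
    for c in final_calls:
        counts = []
        for cohort in (local, global_):
            n = sum(cohort.carrier_count(v)[0] for v in c.variants)
            counts.append(n)
        c.control_carrier_counts = tuple(counts)
    return {"log": log, "stage1_calls": fitting, "final_calls": final_calls,
            "survivors": survivors}
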