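"""Synthetic flocks, funnel fixtures and toy genes with known ground truth.

The flock generator emulates a half-sib livestock design built around two
loss-of-function alleles of one gene: an ungenotyped *grandsire* carries
variant A and sires the ewe cohort, so each ewe inherits A with
probability 1/2; the single genotyped *sire* of all lambs carries
variant B; a lamb is affected iff it carries both A (maternally) and B
(paternally), i.e. the disease is compound-heterozygous with full
penetrance.  A ``recessive`` mode instead makes the sire a son of the
grandsire and plants a single variant, so affected lambs are autozygous
for a grandsire haplotype around the locus.

Array markers are simulated without linkage disequilibrium but with
genetic linkage: crossovers are a Poisson process at 1 cM/Mb (Haldane, no
interference) per meiosis, so co-transmission decays with physical
distance — the property the linkage scan needs.  Every transmission is
recorded as founder-haplotype labels (:class:`FlockTruth`), which serve as
the exact IBD oracle for the estimators, and the emitted genotypes are
audited against those labels at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from comphet.io_formats import (GenotypeMatrix, VariantRecord,
                                HOM_REF, HET, HOM_ALT, MISSING,
                                write_genotypes, write_vcf)
from comphet.linkage import LinkedRegion
from comphet.pedigree import Individual, Pedigree, write_fam
from comphet.variant_filter import ControlCohort
from comphet.consequence import TranscriptModel


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class FlockConfig:
    """Study-design parameters of the simulated flock.

    Defaults mirror the emulated design: 52 ewes, one sire, 18 lambs of
    which 5 are affected, ~2% missing array calls, a 60-genome local and a
    453-genome global control cohort, full penetrance.  ``n_affected=None``
    releases the affected count to its natural binomial draw (at least
    ``min_affected`` affecteds are still required, by redraw).
    """

    n_ewes: int = 52
    n_lambs: int = 18
    n_affected: int | None = 5
    min_affected: int = 2
    n_array_markers: int = 5000
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    freq_low: float = 0.1
    freq_high: float = 0.9
    missingness: float = 0.02
    genotype_error: float = 0.0
    n_local_controls: int = 60
    n_global_controls: int = 453
    n_decoy_variants: int = 30
    n_genotyped_unaffected: int = 3
    penetrance: float = 1.0
    mode: str = "compound_het"  # or "recessive"
    causal_chrom: str = "3"
    causal_pos_a: int = 50_000_000
    causal_pos_b: int = 50_010_000
    causal_gene: str = "geneC"
    max_redraws: int = 5000
    seed: int | None = None  # mandatory

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("FlockConfig.seed is mandatory")
        for name in ("n_ewes", "n_lambs", "n_array_markers", "n_chromosomes",
                     "chrom_length_bp", "n_local_controls", "n_global_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missingness", "genotype_error", "penetrance",
                     "freq_low", "freq_high"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.mode not in ("compound_het", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_affected is not None and not (
                0 < self.n_affected <= self.n_lambs):
            raise ValueError("n_affected must be in (0, n_lambs]")


# ---------------------------------------------------------------------------
# Meioses over a global marker grid
# ---------------------------------------------------------------------------

CM_PER_MB = 1.0  # Haldane map, 1 cM/Mb, no interference


def _meiosis_parity(rng: np.random.Generator, n_chrom: int, chrom_len: int,
                    grid_global: np.ndarray,
                    grid_chrom: np.ndarray) -> np.ndarray:
    """Which parental haplotype (0/1) a gamete carries at each grid point."""
    expected_x = chrom_len / 1e6 * CM_PER_MB / 100.0
    n_x = rng.poisson(expected_x, size=n_chrom)
    start = rng.integers(0, 2, size=n_chrom)
    total = int(n_x.sum())
    if total:
        chrom_of_x = np.repeat(np.arange(n_chrom), n_x)
        xpos = chrom_of_x * chrom_len + rng.uniform(0, chrom_len, total)
        xpos.sort()
        n_before = np.searchsorted(xpos, grid_global)
    else:
        n_before = np.zeros(len(grid_global), dtype=np.int64)
    return (start[grid_chrom] + n_before) % 2


# ---------------------------------------------------------------------------
# Flock truth
# ---------------------------------------------------------------------------


@dataclass
class FlockTruth:
    """Ground truth: founder-haplotype labels and planted-variant carriage."""

    founder_haps: dict[str, np.ndarray]   # sample -> (2, n_markers) founder ids
    clean_calls: dict[str, np.ndarray]    # pre-error, pre-missingness genotypes
    carriers_a: set[str]
    carriers_b: set[str]
    causal_gene: str
    causal_positions: list[tuple[str, int]]
    variant_origin: dict[str, dict[str, str]]  # affected -> {"A": "maternal", ...}

    def autozygous_segments(self, sample: str, chrom: np.ndarray,
                            pos: np.ndarray) -> list[tuple[str, int, int]]:
        """Maximal marker runs where both haplotypes share a founder id."""
        h = self.founder_haps[sample]
        ibd = h[0] == h[1]
        segs = []
        for c in dict.fromkeys(chrom):
            idx = np.flatnonzero(chrom == c)
            flags = ibd[idx]
            k = 0
            while k < len(idx):
                if not flags[k]:
                    k += 1
                    continue
                j = k
                while j + 1 < len(idx) and flags[j + 1]:
                    j += 1
                segs.append((str(c), int(pos[idx[k]]), int(pos[idx[j]]) + 1))
                k = j + 1
        return segs


# ---------------------------------------------------------------------------
# Flock simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFlock:
    config: FlockConfig
    pedigree: Pedigree
    gm: GenotypeMatrix
    family_variants: list[VariantRecord]
    causal_variants: list[VariantRecord]    # genotypes over sequenced samples
    census_variants: list[VariantRecord]    # genotypes over the whole flock
    local_controls: ControlCohort
    global_controls: ControlCohort
    truth: FlockTruth
    sequenced: list[str]
    cases: list[str]        # sequenced affected lambs
    affected: list[str]     # all affected lambs

    @property
    def trios(self) -> list[tuple[str, str, str]]:
        out = []
        for c in self.cases:
            out.append((c, self.pedigree[c].sire_id, self.pedigree[c].dam_id))
        return out

    def write(self, outdir: str) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_genotypes(self.gm, os.path.join(outdir, "flock.ped"),
                        os.path.join(outdir, "flock.map"), self.pedigree)
        write_fam(self.pedigree, os.path.join(outdir, "flock.fam"))
        write_vcf(self.family_variants, os.path.join(outdir, "family.vcf"),
                  sample_ids=self.sequenced)
        for cohort, fname in ((self.local_controls, "local_counts.tsv"),
                              (self.global_controls, "global_counts.tsv")):
            with open(os.path.join(outdir, fname), "w") as fh:
                fh.write("chrom\tpos\tref\talt\tcarriers\tn_samples\n")
                for (chrom, pos, ref, alt), n in sorted(cohort.counts.items()):
                    fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{n}\t"
                             f"{cohort.n_samples}\n")


def simulate_flock(config: FlockConfig) -> SimulatedFlock:
    """Simulate pedigree, array genotypes, variant cohorts and truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length_bp
    n_chrom = cfg.n_chromosomes
    chrom_names = np.array([str(i + 1) for i in range(n_chrom)], dtype=object)

    # marker grid + hidden causal loci
    per_chrom = np.full(n_chrom, cfg.n_array_markers // n_chrom)
    per_chrom[: cfg.n_array_markers % n_chrom] += 1
    causal_c = int(np.flatnonzero(chrom_names == cfg.causal_chrom)[0])
    causal_pos = [cfg.causal_pos_a] if cfg.mode == "recessive" else \
        [cfg.causal_pos_a, cfg.causal_pos_b]
    m_chrom_idx, m_pos = [], []
    for c in range(n_chrom):
        need = int(per_chrom[c])
        forbidden = np.array(causal_pos) if c == causal_c else np.array([], int)
        vals = np.array([], dtype=np.int64)
        while len(vals) < need:
            draw = rng.integers(0, L, size=need + 64)
            vals = np.unique(np.concatenate([vals, draw]))
            vals = vals[~np.isin(vals, forbidden)]
        pick = rng.choice(len(vals), size=need, replace=False)
        m_chrom_idx.append(np.full(need, c))
        m_pos.append(np.sort(vals[pick]))
    m_chrom_idx = np.concatenate(m_chrom_idx)
    m_pos = np.concatenate(m_pos)

    grid_chrom = np.concatenate([m_chrom_idx, np.full(len(causal_pos), causal_c)])
    grid_pos = np.concatenate([m_pos, np.array(causal_pos)])
    order = np.lexsort((grid_pos, grid_chrom))
    grid_chrom, grid_pos = grid_chrom[order], grid_pos[order]
    grid_global = grid_chrom * L + grid_pos
    is_marker = np.ones(len(grid_pos), dtype=bool)
    causal_idx = []
    for cp in causal_pos:
        k = int(np.flatnonzero((grid_chrom == causal_c) & (grid_pos == cp))[0])
        causal_idx.append(k)
        is_marker[k] = False
    n_grid = len(grid_pos)

    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=n_grid)

    # founder haplotypes: GS (ids 0,1), one maternal founder per ewe,
    # and the sire's founder haplotypes
    ewe_ids = [f"EW{i + 1:02d}" for i in range(cfg.n_ewes)]
    founder_names = ["GS.0", "GS.1"] + [f"{e}.mat" for e in ewe_ids]
    sire_from_gs = cfg.mode == "recessive"
    if sire_from_gs:
        founder_names += ["RAM.mat"]
    else:
        founder_names += ["RAM.0", "RAM.1"]
    n_founders = len(founder_names)
    founder_alleles = (rng.random((n_founders, n_grid)) < freqs).astype(np.int8)

    GS0 = 0
    RAM_B_HAP = founder_names.index("RAM.0") if not sire_from_gs else None

    def meiosis(parent_haps):
        parity = _meiosis_parity(rng, n_chrom, L, grid_global, grid_chrom)
        return np.where(parity == 0, parent_haps[0], parent_haps[1])

    # ewes: paternal from GS, maternal founder
    gs_haps = (np.full(n_grid, 0, dtype=np.int16), np.full(n_grid, 1, dtype=np.int16))
    ewe_haps = {}
    for i, e in enumerate(ewe_ids):
        ewe_haps[e] = (meiosis(gs_haps).astype(np.int16),
                       np.full(n_grid, 2 + i, dtype=np.int16))

    # sire: in recessive mode a son of GS, conditioned to carry the causal
    # haplotype; otherwise an unrelated founder carrying variant B on hap 0
    a_idx = causal_idx[0]
    if sire_from_gs:
        for _ in range(cfg.max_redraws):
            pat = meiosis(gs_haps).astype(np.int16)
            if pat[a_idx] == GS0:
                break
        else:
            raise RuntimeError("could not draw a carrier sire")
        ram_haps = (pat, np.full(n_grid, founder_names.index("RAM.mat"),
                                 dtype=np.int16))
    else:
        ram_haps = (np.full(n_grid, RAM_B_HAP, dtype=np.int16),
                    np.full(n_grid, founder_names.index("RAM.1"), dtype=np.int16))

    # lambs: redraw the whole lamb generation until the affected-count
    # condition is met (exact n_affected with distinct dams, or
    # >= min_affected when free)
    lamb_ids = [f"L{i + 1:02d}" for i in range(cfg.n_lambs)]
    b_idx = causal_idx[-1]

    def lamb_carries(haps, idx, founder_hap):
        return haps[0][idx] == founder_hap or haps[1][idx] == founder_hap

    for _ in range(cfg.max_redraws):
        lamb_dams = [ewe_ids[k] for k in rng.integers(0, cfg.n_ewes, cfg.n_lambs)]
        lamb_haps = {}
        affected = []
        for lid, dam in zip(lamb_ids, lamb_dams):
            h = (meiosis(ram_haps).astype(np.int16),
                 meiosis(ewe_haps[dam]).astype(np.int16))
            lamb_haps[lid] = h
            if cfg.mode == "recessive":
                is_aff = h[0][a_idx] == GS0 and h[1][a_idx] == GS0
            else:
                has_a = lamb_carries(h, a_idx, GS0)
                has_b = lamb_carries(h, b_idx, RAM_B_HAP)
                is_aff = has_a and has_b
            if is_aff and rng.random() < cfg.penetrance:
                affected.append(lid)
        if cfg.n_affected is None:
            if len(affected) >= cfg.min_affected:
                break
        else:
            dams_of_aff = [lamb_dams[lamb_ids.index(a)] for a in affected]
            if (len(affected) == cfg.n_affected
                    and len(set(dams_of_aff)) == len(dams_of_aff)):
                break
    else:
        raise RuntimeError(
            f"no draw met the affected-lamb condition in {cfg.max_redraws} tries")

    # pedigree
    inds = [Individual("GS", sex="male", phantom=True)]
    for e in ewe_ids:
        inds.append(Individual(e, sire_id="GS", sex="female",
                               phenotype="unaffected"))
    inds.append(Individual("RAM", sire_id="GS" if sire_from_gs else None,
                           sex="male", phenotype="unaffected"))
    lamb_sex = rng.choice(["male", "female"], size=cfg.n_lambs)
    for lid, dam, sx in zip(lamb_ids, lamb_dams, lamb_sex):
        inds.append(Individual(lid, sire_id="RAM", dam_id=dam, sex=str(sx),
                               phenotype="affected" if lid in affected
                               else "unaffected"))
    ped = Pedigree(inds)

    # carriage of the planted variants across the flock
    all_haps = {"RAM": ram_haps, **ewe_haps, **lamb_haps}
    carriers_a = {s for s, h in all_haps.items() if lamb_carries(h, a_idx, GS0)}
    if cfg.mode == "recessive":
        carriers_b = set()
        hom_a = {s for s, h in all_haps.items()
                 if h[0][a_idx] == GS0 and h[1][a_idx] == GS0}
    else:
        carriers_b = {s for s, h in all_haps.items()
                      if lamb_carries(h, b_idx, RAM_B_HAP)}
        hom_a = set()

    # genotyped sample set: sire, dams of affected, affected lambs, a few
    # unaffected lambs
    dams_of_aff = []
    for a in affected:
        d = lamb_dams[lamb_ids.index(a)]
        if d not in dams_of_aff:
            dams_of_aff.append(d)
    unaff_genotyped = [l for l in lamb_ids if l not in affected][
        : cfg.n_genotyped_unaffected]
    genotyped = ["RAM"] + dams_of_aff + list(affected) + unaff_genotyped

    marker_sel = np.flatnonzero(is_marker)
    founder_haps = {}
    clean_calls = {}
    for s in genotyped:
        h0, h1 = all_haps[s]
        founder_haps[s] = np.vstack([h0[marker_sel], h1[marker_sel]])
        g = (founder_alleles[h0[marker_sel], marker_sel]
             + founder_alleles[h1[marker_sel], marker_sel]).astype(np.int8)
        clean_calls[s] = g

    calls = np.vstack([clean_calls[s] for s in genotyped])
    # self-audit: genotypes must reproduce from the truth labels
    for i, s in enumerate(genotyped):
        hh = founder_haps[s]
        audit = founder_alleles[hh[0], marker_sel] + founder_alleles[hh[1], marker_sel]
        assert np.array_equal(audit.astype(np.int8), calls[i]), "truth audit failed"

    if cfg.genotype_error > 0:
        err = rng.random(calls.shape) < cfg.genotype_error
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missingness > 0:
        calls = np.where(rng.random(calls.shape) < cfg.missingness,
                         MISSING, calls).astype(np.int8)

    gm = GenotypeMatrix(
        sample_ids=genotyped,
        marker_ids=[f"SNP{k + 1}" for k in range(len(marker_sel))],
        chrom=chrom_names[grid_chrom[marker_sel]],
        pos=grid_pos[marker_sel],
        calls=calls)

    # sequenced subset: sire + two complete trios
    cases = affected[:2]
    seq_dams = []
    for c in cases:
        d = lamb_dams[lamb_ids.index(c)]
        if d not in seq_dams:
            seq_dams.append(d)
    sequenced = ["RAM"] + seq_dams + cases

    def gt_of(sample, carriers, hom=frozenset()):
        if sample in hom:
            return HOM_ALT
        return HET if sample in carriers else HOM_REF

    causal_variants = []
    census_variants = []
    if cfg.mode == "recessive":
        var_r = VariantRecord(cfg.causal_chrom, cfg.causal_pos_a, "C", "T",
                              gene_id=cfg.causal_gene, effect_class="missense",
                              var_id="varR",
                              genotypes={s: gt_of(s, carriers_a, hom_a)
                                         for s in sequenced})
        causal_variants = [var_r]
        census_variants = [VariantRecord(
            cfg.causal_chrom, cfg.causal_pos_a, "C", "T",
            gene_id=cfg.causal_gene, effect_class="missense", var_id="varR",
            genotypes={s: gt_of(s, carriers_a, hom_a) for s in all_haps})]
    else:
        var_a = VariantRecord(cfg.causal_chrom, cfg.causal_pos_a, "T", "C",
                              gene_id=cfg.causal_gene,
                              effect_class="splice_acceptor", var_id="varA",
                              genotypes={s: gt_of(s, carriers_a)
                                         for s in sequenced})
        var_b = VariantRecord(cfg.causal_chrom, cfg.causal_pos_b, "G", "A",
                              gene_id=cfg.causal_gene, effect_class="missense",
                              var_id="varB",
                              genotypes={s: gt_of(s, carriers_b)
                                         for s in sequenced})
        causal_variants = [var_a, var_b]
        census_variants = [
            VariantRecord(v.chrom, v.pos, v.ref, v.alt, gene_id=v.gene_id,
                          effect_class=v.effect_class, var_id=v.var_id,
                          genotypes={s: gt_of(s, carr) for s in all_haps})
            for v, carr in ((var_a, carriers_a), (var_b, carriers_b))]

    family_variants, local_counts, global_counts = _make_decoys(
        cfg, rng, chrom_names, sequenced, cases)
    for v in causal_variants:
        local_counts[v.key] = 0
        global_counts[v.key] = 0
    family_variants = causal_variants + family_variants

    truth = FlockTruth(
        founder_haps=founder_haps, clean_calls=clean_calls,
        carriers_a=carriers_a, carriers_b=carriers_b,
        causal_gene=cfg.causal_gene,
        causal_positions=[(cfg.causal_chrom, p) for p in causal_pos],
        variant_origin={a: ({"A": "maternal", "B": "paternal"}
                            if cfg.mode == "compound_het" else
                            {"R": "biparental"}) for a in affected})

    return SimulatedFlock(
        config=cfg, pedigree=ped, gm=gm,
        family_variants=family_variants, causal_variants=causal_variants,
        census_variants=census_variants,
        local_controls=ControlCohort(local_counts, cfg.n_local_controls, "local"),
        global_controls=ControlCohort(global_counts, cfg.n_global_controls, "global"),
        truth=truth, sequenced=sequenced, cases=cases, affected=list(affected))


_DECOY_EFFECTS = ["missense", "missense", "nonsense", "frameshift",
                  "synonymous", "non_coding", "inframe_indel"]
_BASES = "ACGT"


def _make_decoys(cfg, rng, chrom_names, sequenced, cases):
    """Background decoy variants plus the two funnel-relevant planted decoys."""
    variants: list[VariantRecord] = []
    local: dict[tuple, int] = {}
    global_: dict[tuple, int] = {}

    def random_site(i):
        chrom = str(chrom_names[rng.integers(0, len(chrom_names))])
        pos = int(rng.integers(1_000_000, cfg.chrom_length_bp - 1_000_000))
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        return chrom, pos, ref, alt

    # a private recessive-looking decoy that survives every filter
    chrom, pos, ref, alt = random_site(0)
    gts = {s: HOM_ALT if s in cases else HET for s in sequenced}
    v = VariantRecord(chrom, pos, ref, alt, gene_id="decoyR",
                      effect_class="missense", var_id="decoyR", genotypes=gts)
    variants.append(v)
    local[v.key] = 0
    global_[v.key] = 0

    # a recessive-looking decoy that the global cohort removes
    chrom, pos, ref, alt = random_site(1)
    gts = {s: HOM_ALT if s in cases else HET for s in sequenced}
    v = VariantRecord(chrom, pos, ref, alt, gene_id="decoyG",
                      effect_class="missense", var_id="decoyG", genotypes=gts)
    variants.append(v)
    local[v.key] = 0
    global_[v.key] = int(rng.integers(1, 6))

    for i in range(cfg.n_decoy_variants):
        chrom, pos, ref, alt = random_site(i + 2)
        effect = _DECOY_EFFECTS[rng.integers(0, len(_DECOY_EFFECTS))]
        gts = {s: int(rng.choice([HOM_REF, HET, HOM_ALT], p=[0.5, 0.4, 0.1]))
               for s in sequenced}
        v = VariantRecord(chrom, pos, ref, alt, gene_id=f"decoy{i}",
                          effect_class=effect, var_id=f"decoy{i}",
                          genotypes=gts)
        variants.append(v)
        local[v.key] = int(rng.poisson(1.5))
        global_[v.key] = int(rng.poisson(4.0))
    return variants, local, global_


# ---------------------------------------------------------------------------
# Funnel fixture: planted counts 6 -> 4
# ---------------------------------------------------------------------------


def make_funnel_fixture(seed: int = 0) -> dict:
    """A deterministic family VCF + control data with planted funnel fates.

    Six variants survive the protein-changing + local-privacy + inheritance
    stage (the causal compound-het pair, a recessive decoy, a decoy
    compound-het pair, and a recessive decoy later caught globally); exactly
    two of them are carried in the global cohort, leaving four.  Earlier
    stages are exercised by additional decoys that fail them.
    """
    sire, dam1, dam2, case1, case2 = "RAM", "DAM1", "DAM2", "CASE1", "CASE2"
    sequenced = [sire, dam1, dam2, case1, case2]
    cases = [case1, case2]
    trios = [(case1, sire, dam1), (case2, sire, dam2)]
    ped = Pedigree([
        Individual(sire, sex="male", phenotype="unaffected"),
        Individual(dam1, sex="female", phenotype="unaffected"),
        Individual(dam2, sex="female", phenotype="unaffected"),
        Individual(case1, sire_id=sire, dam_id=dam1, phenotype="affected"),
        Individual(case2, sire_id=sire, dam_id=dam2, phenotype="affected"),
    ])

    def rec(chrom, pos, ref, alt, gene, effect, pattern, var_id):
        pats = {
            "maternal_het": {sire: HOM_REF, dam1: HET, dam2: HET,
                             case1: HET, case2: HET},
            "paternal_het": {sire: HET, dam1: HOM_REF, dam2: HOM_REF,
                             case1: HET, case2: HET},
            "recessive": {sire: HET, dam1: HET, dam2: HET,
                          case1: HOM_ALT, case2: HOM_ALT},
            "one_case": {sire: HET, dam1: HOM_REF, dam2: HOM_REF,
                         case1: HET, case2: HOM_REF},
        }
        return VariantRecord(chrom, pos, ref, alt, gene_id=gene,
                             effect_class=effect, var_id=var_id,
                             genotypes=dict(pats[pattern]))

    v1 = rec("3", 50_000_000, "T", "C", "geneC", "splice_acceptor",
             "maternal_het", "causalA")
    v2 = rec("3", 50_010_000, "G", "A", "geneC", "missense",
             "paternal_het", "causalB")
    v3 = rec("15", 50_640_253, "C", "T", "decoyR", "missense",
             "recessive", "decoyR")
    v4 = rec("7", 30_000_000, "A", "G", "decoyH", "missense",
             "paternal_het", "decoyH1")
    v5 = rec("7", 30_050_000, "C", "A", "decoyH", "missense",
             "maternal_het", "decoyH2")
    v6 = rec("9", 10_000_000, "G", "T", "decoyG", "nonsense",
             "recessive", "decoyG")
    # stage-failing decoys
    v7 = rec("2", 5_000_000, "A", "C", "decoyS", "synonymous",
             "recessive", "decoyS")
    v8 = rec("4", 8_000_000, "T", "G", "decoyL", "missense",
             "recessive", "decoyL")
    v9 = rec("5", 9_000_000, "G", "C", "decoyO", "missense",
             "one_case", "decoyO")
    variants = [v1, v2, v3, v4, v5, v6, v7, v8, v9]

    local = {v.key: 0 for v in variants}
    local[v8.key] = 3  # seen in the local cohort -> removed early
    global_ = {v.key: 0 for v in variants}
    global_[v5.key] = 2  # breaks the decoy pair
    global_[v6.key] = 5  # removes the second recessive decoy

    linked_regions = [LinkedRegion(chrom="3", start=49_500_000,
                                   end=50_500_000, n_markers=30,
                                   max_Z=3.2, max_LOD=float(3.2 ** 2 / (2 * np.log(10))))]
    return {"variants": variants, "pedigree": ped, "trios": trios,
            "cases": cases, "sequenced": sequenced,
            "local": ControlCohort(local, 60, "local"),
            "global": ControlCohort(global_, 453, "global"),
            "linked_regions": linked_regions, "shared_roh": [],
            "causal_pair": (v1, v2)}


# ---------------------------------------------------------------------------
# Toy genes for the consequence engine
# ---------------------------------------------------------------------------

_SAFE_CODONS = ["GCT", "GAA", "CTG", "AAG", "GAT", "TTC", "GGA", "CAC",
                "ATC", "AAA", "ATG", "CCA", "TCT", "GTG", "TAC", "CAA"]


def _random_codons(rng, n):
    return [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n)]


def _random_intron(rng, n):
    body = "".join(_BASES[i] for i in rng.integers(0, 4, size=n - 4))
    return "GT" + body + "AG"


def _mirror(model: TranscriptModel, variant: VariantRecord,
            new_chrom: str) -> tuple[TranscriptModel, VariantRecord]:
    """Reverse-complement mirror of a model + variant (strand flipped)."""
    seq = model.chrom_seq()
    L = len(seq)
    rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
    exons = sorted((L - e, L - s) for s, e in model.exons)
    m = TranscriptModel(
        model.transcript_id + "_rev", model.gene_id + "_rev", new_chrom,
        "-" if model.strand == "+" else "+", exons,
        L - model.cds_end, L - model.cds_start, seq={new_chrom: rc})
    comp = str.maketrans("ACGT", "TGCA")
    v = VariantRecord(new_chrom, L - 1 - variant.pos,
                      variant.ref.translate(comp), variant.alt.translate(comp),
                      gene_id=model.gene_id + "_rev",
                      var_id=(variant.var_id or "v") + "_rev")
    return m, v


@dataclass
class ToyGenes:
    models: dict[str, TranscriptModel]
    variants: dict[str, VariantRecord]

    def all_models(self) -> list[TranscriptModel]:
        return list(self.models.values())


def make_toy_genes(seed: int = 0) -> ToyGenes:
    """Construct toy gene models with engineered consequence properties.

    * ``acceptor``: a 4-exon gene whose exon-3 acceptor loss activates a
      cryptic AG 10 bases into the exon; the resulting frameshift diverges
      at residue 71 (Leu->Trp) and stops at the third new-frame codon, so
      the mutant protein has 72 residues and loses >90% of the reference.
    * ``iso_short``/``iso_long``: two isoforms sharing exons; the long one
      includes a proline-rich insert exon that re-splits the junction
      codon, so one genomic C>T is a nonsense Gln->Ter on the short isoform
      and a missense Leu->Phe on the long one.
    * reverse-strand mirrors of each, for strand-symmetry checks.

    All structural claims are verified at construction time.
    """
    rng = np.random.default_rng(seed)

    # ---- gene (a): acceptor-loss toy ----
    # codons 70..77 engineered; the rest is stop-free filler
    codons = (["ATG"] + _random_codons(rng, 68) + ["CTG"]
              + ["CTT", "CCC", "CAG", "CTG", "GCA", "TTG", "ACT"]
              + _random_codons(rng, 739 - 77) + ["TAA"])
    cds = "".join(codons)
    assert len(cds) == 2220
    utr5 = "".join(_BASES[i] for i in rng.integers(0, 4, size=20))
    utr3 = "".join(_BASES[i] for i in rng.integers(0, 4, size=30))
    # exon boundaries in CDS coordinates: 100 | 209 | 609 | end
    e1_seq = utr5 + cds[:100]
    e2_seq = cds[100:209]
    e3_seq = cds[209:609]
    e4_seq = cds[609:] + utr3
    assert e3_seq[:10] == "GCTTCCCCAG" and "AG" not in e3_seq[:9]
    i1, i2, i3 = (_random_intron(rng, 80) for _ in range(3))
    genome = e1_seq + i1 + e2_seq + i2 + e3_seq + i3 + e4_seq
    off = 0
    exons = []
    for part, is_exon in ((e1_seq, True), (i1, False), (e2_seq, True),
                          (i2, False), (e3_seq, True), (i3, False),
                          (e4_seq, True)):
        if is_exon:
            exons.append((off, off + len(part)))
        off += len(part)
    cds_start = len(utr5)
    cds_end = len(genome) - len(utr3)
    acceptor = TranscriptModel("toyA.t1", "toyA", "chrA", "+", exons,
                               cds_start, cds_end, seq={"chrA": genome})
    assert acceptor.cds == cds and len(acceptor.protein_seq) == 739
    # the acceptor A of intron 2 (position c.210-2)
    a_pos = exons[2][0] - 2
    assert genome[a_pos] == "A" and genome[a_pos + 1] == "G"
    var_acc = VariantRecord("chrA", a_pos, "A", "G", gene_id="toyA",
                            var_id="toyA_acc")

    # ---- gene (b): two isoforms with an insert exon ----
    codons_s = (["ATG"] + _random_codons(rng, 394)
                + ["CAG"] + _random_codons(rng, 394) + ["TAA"])
    cds_s = "".join(codons_s)
    assert len(cds_s) == 2373
    utr5b = "".join(_BASES[i] for i in rng.integers(0, 4, size=20))
    utr3b = "".join(_BASES[i] for i in rng.integers(0, 4, size=30))
    # shared exons in CDS coordinates: 300 | 700 | 1186 | end; the insert
    # exon sits between the 3rd and 4th and re-splits the junction codon
    e1 = utr5b + cds_s[:300]
    e2 = cds_s[300:700]
    e3 = cds_s[700:1186]          # ends with the junction C of codon 396
    e4 = cds_s[1186:] + utr3b     # begins AG, completing Gln396 in the short
    assert cds_s[1185] == "C" and cds_s[1186:1188] == "AG"
    insert_codons = ["CCT", "CCA", "CCG"] * 18
    insert = "TT" + "".join(insert_codons) + "C"
    assert len(insert) == 165
    j1, j2, j3, j4 = (_random_intron(rng, 80) for _ in range(4))
    genome_b = e1 + j1 + e2 + j2 + e3 + j3 + insert + j4 + e4
    offs = {}
    off = 0
    for name, part in (("e1", e1), ("j1", j1), ("e2", e2), ("j2", j2),
                       ("e3", e3), ("j3", j3), ("ins", insert), ("j4", j4),
                       ("e4", e4)):
        offs[name] = (off, off + len(part))
        off += len(part)
    cds_start_b = len(utr5b)
    cds_end_b = len(genome_b) - len(utr3b)
    seqs_b = {"chrB": genome_b}
    iso_short = TranscriptModel(
        "toyB.short", "toyB", "chrB", "+",
        [offs["e1"], offs["e2"], offs["e3"], offs["e4"]],
        cds_start_b, cds_end_b, seq=seqs_b)
    iso_long = TranscriptModel(
        "toyB.long", "toyB", "chrB", "+",
        [offs["e1"], offs["e2"], offs["e3"], offs["ins"], offs["e4"]],
        cds_start_b, cds_end_b, seq=seqs_b)
    assert len(iso_short.protein_seq) == 790
    assert len(iso_long.protein_seq) == 790 + 55
    assert iso_short.protein_seq[395] == "Q" and iso_long.protein_seq[395] == "L"
    # the variant: C>T at the last base of shared exon 3
    v_pos = offs["e3"][1] - 1
    assert genome_b[v_pos] == "C"
    var_iso = VariantRecord("chrB", v_pos, "C", "T", gene_id="toyB",
                            var_id="toyB_snv")

    acceptor_rev, var_acc_rev = _mirror(acceptor, var_acc, "chrA_rev")
    iso_short_rev, var_iso_rev = _mirror(iso_short, var_iso, "chrB_rev")
    iso_long_rev, _ = _mirror(iso_long, var_iso, "chrB_rev")

    return ToyGenes(
        models={"acceptor": acceptor, "acceptor_rev": acceptor_rev,
                "iso_short": iso_short, "iso_long": iso_long,
                "iso_short_rev": iso_short_rev, "iso_long_rev": iso_long_rev},
        variants={"acceptor": var_acc, "acceptor_rev": var_acc_rev,
                  "iso": var_iso, "iso_rev": var_iso_rev})


# ---------------------------------------------------------------------------
# The printed segregation census as an exact fixture
# ---------------------------------------------------------------------------


def encode_fig2a_fixture() -> dict:
    """The full-flock two-variant genotyping outcome, exact by construction.

    71 animals: 1 sire heterozygous for the paternal-line variant B; 52
    ewes of which 27 are heterozygous for the maternal-line variant A and
    25 wild type; 5 affected lambs heterozygous for both; 13 unaffected
    lambs split 3 wild type / 7 het-B / 3 het-A.  All ewes are daughters
    of one ungenotyped (phantom) grandsire.
    """
    inds = [Individual("GS", sex="male", phantom=True)]
    ewes = [f"EW{i + 1:02d}" for i in range(52)]
    het_a_ewes = set(ewes[:27])
    for e in ewes:
        inds.append(Individual(e, sire_id="GS", sex="female",
                               phenotype="unaffected"))
    inds.append(Individual("RAM", sex="male", phenotype="unaffected"))
    aff = [f"AL{i + 1}" for i in range(5)]
    for i, a in enumerate(aff):
        inds.append(Individual(a, sire_id="RAM", dam_id=ewes[i],
                               phenotype="affected"))
    unaff = [f"UL{i + 1}" for i in range(13)]
    # 3 WT, 7 het-B, 3 het-A; het-A lambs need carrier dams
    dams_unaff = ewes[30:40] + ewes[5:8]
    for u, d in zip(unaff, dams_unaff):
        inds.append(Individual(u, sire_id="RAM", dam_id=d,
                               phenotype="unaffected"))
    ped = Pedigree(inds)

    samples = ["RAM"] + ewes + aff + unaff
    gt_a, gt_b = {}, {}
    for s in samples:
        a = b = HOM_REF
        if s in het_a_ewes or s in aff or s in unaff[10:13]:
            a = HET
        if s == "RAM" or s in aff or s in unaff[3:10]:
            b = HET
        gt_a[s], gt_b[s] = a, b
    var_a = VariantRecord("3", 50_000_000, "T", "C", gene_id="geneC",
                          effect_class="splice_acceptor", var_id="varA",
                          genotypes=gt_a)
    var_b = VariantRecord("3", 50_010_000, "G", "A", gene_id="geneC",
                          effect_class="missense", var_id="varB",
                          genotypes=gt_b)
    return {"pedigree": ped, "var_a": var_a, "var_b": var_b,
            "samples": samples, "ewes": ewes, "affected": aff,
            "unaffected_lambs": unaff}
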