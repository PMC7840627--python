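"""Nonparametric allele-sharing linkage scan with a gene-drop null.

The statistic is a singlepoint pairs statistic: for every pair of affected
animals, the expected number of alleles shared identical-by-descent (IBD)
through their shared parents, conditional on the single-marker genotypes of
the two children and their parents, normalised by 2 (so a fully shared
full-sib pair contributes 1.0 and a half-sib pair at most 0.5).  IBD is
deduced exactly where parental genotypes make the transmitted haplotype
unambiguous, and set to its conditional expectation otherwise; pairs whose
shared parent is homozygous (or any required genotype missing) are
uninformative and sit at their pedigree prior.  ``S_obs`` sums the pair
values; a marker where no pair is informative is flagged undefined.

The null is Monte-Carlo gene drop: founder alleles are drawn at the
marker's folded founder allele frequency and transmitted through the
pedigree under Mendelian rules with no linkage to phenotype; the same
estimator — with ungenotyped individuals masked, so the null sees exactly
what the data can show — is applied to each replicate, conditioning on
marker informativeness as the observed scan does.  Because the exact
singlepoint statistic has a skewed, discrete null, the standardised score
is the normal quantile of the empirical mid-p against that null sample
(``Z = Phi^-1(1 - mid-p)``) rather than a moment standardisation; the
empirical mean/sd are still reported, and
``LOD = sign(Z) * Z^2 / (2 ln 10)``.  Folding the frequency makes the
scan exactly invariant to allele relabelling.  Candidate regions are
maximal runs of consecutive markers with Z > 0, bridging up to
``gap_markers`` undefined markers, with genomic bounds extended to the
midpoint toward the nearest contradicting marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from comphet.io_formats import GenotypeMatrix, MISSING
from comphet.pedigree import Pedigree

_LN10_2 = 2.0 * np.log(10.0)

# ---------------------------------------------------------------------------
# Conditional-expectation lookup tables (indices are genotype state + 1,
# so missing=-1 maps to 0).
# ---------------------------------------------------------------------------

_GT_HAPS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _transmission_posterior(shared_gt: int, other_gt: int, child_gt: int):
    """P(shared parent transmitted its first haplotype | genotypes).

    Returns None when the genotypes are Mendelian-inconsistent.  The other
    parent's transmitted allele is marginalised uniformly over its two
    haplotypes.
    """
    sh = _GT_HAPS[shared_gt]
    ot = _GT_HAPS[other_gt]
    w = [0.0, 0.0]
    for h in (0, 1):
        for m in (0, 1):
            if sh[h] + ot[m] == child_gt:
                w[h] += 0.25
    tot = w[0] + w[1]
    return None if tot == 0 else w[0] / tot


def _build_tables():
    # half-sib (one shared parent): value = E[IBD at the shared parent] in
    # [0,1]; full-sib: value = E[paternal IBD] + E[maternal IBD] in [0,2].
    hs_val = np.full((4, 4, 4, 4, 4), 0.5)
    hs_inf = np.zeros((4, 4, 4, 4, 4), dtype=bool)
    for s in (0, 1, 2):
        for di in (0, 1, 2):
            for ci in (0, 1, 2):
                pi = _transmission_posterior(s, di, ci)
                for dj in (0, 1, 2):
                    for cj in (0, 1, 2):
                        pj = _transmission_posterior(s, dj, cj)
                        if pi is None or pj is None:
                            continue  # Mendelian error -> prior, uninformative
                        e = pi * pj + (1 - pi) * (1 - pj)
                        hs_val[s + 1, di + 1, ci + 1, dj + 1, cj + 1] = e
                        # informative iff the posterior moves off the prior:
                        # a pair pinned at 1/2 contributes no discrimination
                        hs_inf[s + 1, di + 1, ci + 1, dj + 1, cj + 1] = (e != 0.5)

    fs_val = np.full((4, 4, 4, 4), 1.0)
    fs_inf = np.zeros((4, 4, 4, 4), dtype=bool)
    for s in (0, 1, 2):
        for d in (0, 1, 2):
            for ci in (0, 1, 2):
                psi = _transmission_posterior(s, d, ci)
                pdi = _transmission_posterior(d, s, ci)
                for cj in (0, 1, 2):
                    psj = _transmission_posterior(s, d, cj)
                    pdj = _transmission_posterior(d, s, cj)
                    if None in (psi, pdi, psj, pdj):
                        continue
                    e_pat = psi * psj + (1 - psi) * (1 - psj)
                    e_mat = pdi * pdj + (1 - pdi) * (1 - pdj)
                    fs_val[s + 1, d + 1, ci + 1, cj + 1] = e_pat + e_mat
                    fs_inf[s + 1, d + 1, ci + 1, cj + 1] = (e_pat + e_mat != 1.0)

    return hs_val, hs_inf, fs_val, fs_inf


_HS_VAL, _HS_INF, _FS_VAL, _FS_INF = _build_tables()


# ---------------------------------------------------------------------------
# Grandsire-aware half-sib pairs.  When the two dams are themselves half-sibs
# through a shared *ungenotyped* sire (the study design), the lambs can share
# maternal alleles IBD through that grandsire.  The conditional expectation
# marginalises every latent transmission exactly: the grandsire's two alleles,
# each dam's paternal-haplotype pick and maternal founder allele, each lamb's
# maternal and paternal picks, and the sire's two haplotype alleles — all
# constrained by the observed genotypes, with founder alleles at the marker's
# allele frequency.  The prior (no genotype information) is 1/2 paternal +
# 1/8 maternal IBD, i.e. 0.3125 on the normalised scale.
# ---------------------------------------------------------------------------

_GS_PRIOR = (0.5 + 0.125) / 2.0
# a pair counts as informative when its posterior moves materially off the
# prior; below this the Z sign is Monte-Carlo noise
_GS_EPS = 0.05


def _build_gs_configs():
    """Latent-configuration matrices for the grandsire-aware pair."""
    import itertools
    configs = list(itertools.product(
        (0, 1), (0, 1),          # sire hap alleles s1, s2
        (0, 1), (0, 1),          # grandsire alleles g1, g2
        (0, 1), (0, 1), (0, 1), (0, 1),  # dam_i: u, m ; dam_j: u, m
        (0, 1), (0, 1),          # lamb_i: v (maternal pick), h (paternal pick)
        (0, 1), (0, 1)))         # lamb_j: v, h
    cfg = np.array(configs, dtype=np.int8)
    s1, s2, g1, g2 = cfg[:, 0], cfg[:, 1], cfg[:, 2], cfg[:, 3]
    ui, mi, uj, mj = cfg[:, 4], cfg[:, 5], cfg[:, 6], cfg[:, 7]
    vi, hi, vj, hj = cfg[:, 8], cfg[:, 9], cfg[:, 10], cfg[:, 11]
    g = np.stack([g1, g2])          # grandsire haplotype alleles
    s = np.stack([s1, s2])
    dam_i_pat = g[ui, np.arange(len(cfg))]
    dam_j_pat = g[uj, np.arange(len(cfg))]
    dam_i_gt = dam_i_pat + mi
    dam_j_gt = dam_j_pat + mj
    lamb_i_mat = np.where(vi == 0, dam_i_pat, mi)  # v=0: dam's GS-derived hap
    lamb_j_mat = np.where(vj == 0, dam_j_pat, mj)
    lamb_i_gt = s[hi, np.arange(len(cfg))] + lamb_i_mat
    lamb_j_gt = s[hj, np.arange(len(cfg))] + lamb_j_mat
    sire_gt = s1 + s2
    pat_ibd = (hi == hj).astype(float)
    mat_ibd = ((vi == 0) & (vj == 0) & (ui == uj)).astype(float)
    n_alt = (s1 + s2 + g1 + g2 + mi + mj).astype(np.int8)  # freq exponent

    # consistency mask for every (sire, dam_i, lamb_i, dam_j, lamb_j) genotype
    # combination, missing (-1) meaning unconstrained
    gts = np.array([-1, 0, 1, 2], dtype=np.int8)
    ok_s = (gts[:, None] == -1) | (gts[:, None] == sire_gt[None, :])
    ok_di = (gts[:, None] == -1) | (gts[:, None] == dam_i_gt[None, :])
    ok_ci = (gts[:, None] == -1) | (gts[:, None] == lamb_i_gt[None, :])
    ok_dj = (gts[:, None] == -1) | (gts[:, None] == dam_j_gt[None, :])
    ok_cj = (gts[:, None] == -1) | (gts[:, None] == lamb_j_gt[None, :])
    # mask shape: (4,4,4,4,4, n_cfg)
    mask = (ok_s[:, None, None, None, None, :]
            & ok_di[None, :, None, None, None, :]
            & ok_ci[None, None, :, None, None, :]
            & ok_dj[None, None, None, :, None, :]
            & ok_cj[None, None, None, None, :, :])
    return mask.reshape(4 ** 5, -1), pat_ibd + mat_ibd, n_alt


_GS_MASK, _GS_IBD, _GS_NALT = _build_gs_configs()
_GS_TABLE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _gs_table(freq: float) -> tuple[np.ndarray, np.ndarray]:
    """(value, informative) lookup over the 4^5 genotype combinations."""
    f = round(float(freq), 6)
    if f in _GS_TABLE_CACHE:
        return _GS_TABLE_CACHE[f]
    w = f ** _GS_NALT * (1.0 - f) ** (6 - _GS_NALT)
    denom = _GS_MASK @ w
    numer = _GS_MASK @ (w * _GS_IBD)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(denom > 0, numer / denom, 2 * _GS_PRIOR) / 2.0
    inf = (denom > 0) & (np.abs(val - _GS_PRIOR) > _GS_EPS)
    _GS_TABLE_CACHE[f] = (val, inf)
    return val, inf


# ---------------------------------------------------------------------------
# Pair structure
# ---------------------------------------------------------------------------


@dataclass
class _Pair:
    i: str
    j: str
    kind: str  # "FS", "HS", "HS_GS" or "UNREL"
    shared: str | None = None   # shared parent (HS / HS_GS: the sire)
    other_i: str | None = None  # the unshared parents (the dams for HS_GS)
    other_j: str | None = None
    sire: str | None = None     # FS parents
    dam: str | None = None


def affected_pairs(ped: Pedigree, affecteds: list[str],
                   genotyped: set[str] | None = None) -> list[_Pair]:
    """Pair structure of the affected set.

    A half-sib pair whose dams are themselves half-sibs through a shared
    *ungenotyped* sire is promoted to the grandsire-aware kind, which also
    estimates maternal-path IBD.
    """
    pairs = []
    for a in range(len(affecteds)):
        for b in range(a + 1, len(affecteds)):
            i, j = affecteds[a], affecteds[b]
            si, di = ped[i].sire_id, ped[i].dam_id
            sj, dj = ped[j].sire_id, ped[j].dam_id
            same_sire = si is not None and si == sj
            same_dam = di is not None and di == dj
            if same_sire and same_dam:
                pairs.append(_Pair(i, j, "FS", sire=si, dam=di))
            elif same_sire:
                kind = "HS"
                if (di and dj and di in ped and dj in ped
                        and ped[di].sire_id is not None
                        and ped[di].sire_id == ped[dj].sire_id
                        and (genotyped is None
                             or ped[di].sire_id not in genotyped)):
                    kind = "HS_GS"
                pairs.append(_Pair(i, j, kind, shared=si,
                                   other_i=di, other_j=dj))
            elif same_dam:
                pairs.append(_Pair(i, j, "HS", shared=di, other_i=si, other_j=sj))
            else:
                pairs.append(_Pair(i, j, "UNREL"))
    return pairs


def _sharing_from_genotypes(genos: dict[str, np.ndarray], pairs: list[_Pair],
                            freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised S and any-pair-informative flags over marker columns."""
    n = len(next(iter(genos.values())))
    miss = np.full(n, MISSING, dtype=np.int8)
    freqs = np.asarray(freqs, dtype=float)
    uniq_f = np.unique(np.round(freqs, 6))

    def g(iid):
        if iid is None:
            return miss
        return genos.get(iid, miss)

    S = np.zeros(n)
    any_inf = np.zeros(n, dtype=bool)
    for p in pairs:
        if p.kind == "UNREL":
            continue  # shares 0 alleles IBD by construction
        if p.kind == "FS":
            idx = (g(p.sire) + 1, g(p.dam) + 1, g(p.i) + 1, g(p.j) + 1)
            val, inf = _FS_VAL[idx], _FS_INF[idx]
        elif p.kind == "HS_GS":
            flat = ((((g(p.shared) + 1).astype(np.int64) * 4
                      + (g(p.other_i) + 1)) * 4 + (g(p.i) + 1)) * 4
                    + (g(p.other_j) + 1)) * 4 + (g(p.j) + 1)
            val = np.empty(n)
            inf = np.empty(n, dtype=bool)
            for f in uniq_f:
                tv, ti = _gs_table(f)
                sel = np.round(freqs, 6) == f
                val[sel] = tv[flat[sel]]
                inf[sel] = ti[flat[sel]]
            S += val
            any_inf |= inf
            continue
        else:
            idx = (g(p.shared) + 1, g(p.other_i) + 1, g(p.i) + 1,
                   g(p.other_j) + 1, g(p.j) + 1)
            val, inf = _HS_VAL[idx], _HS_INF[idx]
        S += val / 2.0
        any_inf |= inf
    return S, any_inf


def _canonicalize(genos: dict[str, np.ndarray], freqs: np.ndarray
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Fold each marker to the minor-allele labelling.

    The estimator is symmetric in allele labels; evaluating every marker at
    its folded frequency with correspondingly flipped genotypes makes the
    scan *exactly* invariant to relabelling (no floating-point asymmetry).
    """
    freqs = np.asarray(freqs, dtype=float)
    flip = freqs > 0.5
    out = {}
    for k, v in genos.items():
        flipped = np.where((v >= 0) & flip, 2 - v, v).astype(np.int8)
        out[k] = flipped
    return out, np.where(flip, 1.0 - freqs, freqs)


def pairwise_sharing_statistic(gm: GenotypeMatrix, ped: Pedigree,
                               marker: int, affecteds: list[str],
                               freq: float | None = None) -> float:
    """Observed pairs statistic at one marker; NaN when uninformative."""
    if len(affecteds) < 2:
        raise ValueError("need >= 2 affected individuals")
    pairs = affected_pairs(ped, affecteds, set(gm.sample_ids))
    ids = _estimator_individuals(ped, affecteds)
    genos = {i: gm.calls[gm.sample_index(i), marker:marker + 1]
             for i in ids if i in gm.sample_ids}
    if freq is None:
        freq = float(estimate_founder_freqs(gm, ped, affecteds)[marker])
    S, inf = _sharing_from_genotypes(genos, pairs, np.array([freq]))
    return float(S[0]) if inf[0] else float("nan")


def _estimator_individuals(ped: Pedigree, affecteds: list[str]) -> list[str]:
    ids = []
    for a in affecteds:
        for x in (a, ped[a].sire_id, ped[a].dam_id):
            if x is not None and x not in ids:
                ids.append(x)
    return ids


# ---------------------------------------------------------------------------
# Gene-drop null
# ---------------------------------------------------------------------------


def estimate_founder_freqs(gm: GenotypeMatrix, ped: Pedigree,
                           affecteds: list[str] | None = None) -> np.ndarray:
    """Alt-allele frequency per marker from genotyped founders only.

    Founders here are genotyped samples with no genotyped parent (the dams
    and the sire in the study design); affected individuals are always
    excluded.  Frequencies are clamped away from 0/1 so the null never
    degenerates.
    """
    affected_set = set(affecteds if affecteds is not None
                       else [i.id for i in ped if i.phenotype == "affected"])
    genotyped = set(gm.sample_ids)
    rows = []
    for iid in gm.sample_ids:
        if iid in affected_set:
            continue
        ind = ped[iid] if iid in ped else None
        if ind is not None and (ind.sire_id in genotyped or ind.dam_id in genotyped):
            continue
        rows.append(gm.sample_index(iid))
    if not rows:
        raise ValueError("no genotyped founders to estimate allele frequencies")
    calls = gm.calls[rows]
    ok = calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(ok, calls, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))
    freq = np.nan_to_num(freq, nan=0.5)
    eps = 0.5 / (2.0 * len(rows))
    return np.clip(freq, eps, 1 - eps)


def _drop_subpedigree(ped: Pedigree, affecteds: list[str]) -> list[str]:
    """Affecteds, their parents, and all in-pedigree ancestors, topo-sorted."""
    wanted: set[str] = set()
    stack = list(affecteds)
    while stack:
        x = stack.pop()
        if x in wanted or x not in ped:
            continue
        wanted.add(x)
        stack += [p for p in (ped[x].sire_id, ped[x].dam_id) if p]
    order: list[str] = []
    placed: set[str] = set()
    while len(order) < len(wanted):
        progressed = False
        for x in wanted:
            if x in placed:
                continue
            s, d = ped[x].sire_id, ped[x].dam_id
            if (s not in wanted or s in placed) and (d not in wanted or d in placed):
                order.append(x)
                placed.add(x)
                progressed = True
        if not progressed:  # pragma: no cover - cycles rejected by Pedigree
            raise ValueError("pedigree cycle in gene drop")
    return order


def _drop_once_vectorised(ped: Pedigree, order: list[str], freq: np.ndarray,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Drop founder alleles through the pedigree; columns are replicates."""
    n = len(freq)
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for x in order:
        out = []
        for parent in (ped[x].sire_id, ped[x].dam_id):
            if parent in haps:
                pick = rng.integers(0, 2, size=n)
                out.append(np.where(pick == 0, haps[parent][0], haps[parent][1]))
            else:
                out.append((rng.random(n) < freq).astype(np.int8))
        haps[x] = (out[0], out[1])
    return {x: (h[0] + h[1]).astype(np.int8) for x, h in haps.items()}


def gene_drop_null(ped: Pedigree, freqs: np.ndarray, affecteds: list[str],
                   n_reps: int = 1000, seed: int | None = None,
                   genotyped: set[str] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (mean, sd) of the pairs statistic under no linkage.

    Frequencies are folded (min(f, 1-f)) and markers sharing a folded
    frequency share one batch of ``n_reps`` drops, so the null — and hence
    Z — is exactly invariant to allele relabelling.  Replicates where no
    pair is informative are excluded, matching the observed scan's
    conditioning; if no replicate is informative the unconditional moments
    are returned.
    """
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} < 100: null sd will be unstable")
    if seed is None:
        raise ValueError("gene_drop_null requires an explicit seed")
    freqs = np.asarray(freqs, dtype=float)
    folded = np.minimum(freqs, 1.0 - freqs).round(6)
    samples = _null_samples(ped, np.unique(folded), affecteds, n_reps, seed,
                            genotyped)
    mean = np.empty(len(freqs))
    sd = np.empty(len(freqs))
    for f, use in samples.items():
        sel = folded == f
        mean[sel] = use.mean()
        sd[sel] = use.std(ddof=0)
    return mean, sd


def _null_samples(ped: Pedigree, folded_freqs: np.ndarray,
                  affecteds: list[str], n_reps: int, seed: int,
                  genotyped: set[str] | None) -> dict[float, np.ndarray]:
    """Sorted empirical null sample of S per folded frequency.

    Accumulates until ``n_reps`` *informative* replicates (the observed scan
    conditions on informativeness, so the null must too); at extreme
    frequencies informative replicates are rare, hence the batching.
    Individuals who are not genotyped in the data are masked in the drops
    too, so the null reflects exactly what is observable.
    """
    pairs = affected_pairs(ped, affecteds, genotyped)
    order = _drop_subpedigree(ped, affecteds)
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for f in np.asarray(folded_freqs, dtype=float):
        collected: list[np.ndarray] = []
        n_collected = 0
        fallback = None
        for _ in range(20):
            cols = np.full(n_reps, f)
            genos = _drop_once_vectorised(ped, order, cols, rng)
            if genotyped is not None:
                miss = np.full(n_reps, MISSING, dtype=np.int8)
                genos = {k: (v if k in genotyped else miss)
                         for k, v in genos.items()}
            S, inf = _sharing_from_genotypes(genos, pairs, cols)
            fallback = S
            collected.append(S[inf])
            n_collected += int(inf.sum())
            if n_collected >= n_reps:
                break
        use = np.concatenate(collected) if n_collected else fallback
        out[float(f)] = np.sort(use)
    return out


# ---------------------------------------------------------------------------
# Scan and region merging
# ---------------------------------------------------------------------------


@dataclass
class LinkageParams:
    """``gap_markers`` bridges *undefined* (uninformative) markers inside a
    positive run; with a singlepoint statistic roughly half the markers are
    uninformative for the half-sib design, so breaking on every one of them
    would shatter true regions into single-marker fragments."""
    n_reps: int = 1000
    gap_markers: int = 10
    seed: int | None = None  # mandatory


@dataclass
class LinkedRegion:
    chrom: str
    start: int
    end: int
    n_markers: int
    max_Z: float
    max_LOD: float

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


def scan_and_merge(gm: GenotypeMatrix, ped: Pedigree, affecteds: list[str],
                   params: LinkageParams) -> tuple[pd.DataFrame, list[LinkedRegion]]:
    """Per-marker Z/LOD scan plus merged positive-score regions."""
    if params.seed is None:
        raise ValueError("LinkageParams.seed is mandatory")
    genotyped = set(gm.sample_ids)
    pairs = affected_pairs(ped, affecteds, genotyped)
    ids = _estimator_individuals(ped, affecteds)
    genos = {i: gm.row(i) for i in ids if i in gm.sample_ids}
    freqs = estimate_founder_freqs(gm, ped, affecteds)
    genos, canon_f = _canonicalize(genos, freqs)
    S, inf = _sharing_from_genotypes(genos, pairs, canon_f)
    S = np.where(inf, S, np.nan)

    # standardise against the empirical gene-drop null: the exact singlepoint
    # statistic has a skewed discrete null, so Z is the normal quantile of
    # the mid-p rather than a moment standardisation (which would mis-set
    # the tail the positive-region criterion depends on)
    folded = np.minimum(freqs, 1.0 - freqs).round(6)
    samples = _null_samples(ped, np.unique(folded), affecteds,
                            params.n_reps, params.seed, genotyped)
    mean = np.empty(len(freqs))
    sd = np.empty(len(freqs))
    Z = np.full(len(freqs), np.nan)
    for f, null in samples.items():
        sel = folded == f
        mean[sel] = null.mean()
        sd[sel] = null.std(ddof=0)
        n = len(null)
        use = sel & ~np.isnan(S)
        if sd[sel][0] == 0 or not use.any():
            continue
        lo = np.searchsorted(null, S[use], side="left")
        hi = np.searchsorted(null, S[use], side="right")
        mid_p_upper = (n - hi + 0.5 * (hi - lo)) / n  # P(null > s) + P(=)/2
        eps = 0.5 / n
        Z[use] = stats.norm.isf(np.clip(mid_p_upper, eps, 1 - eps))
    lod = np.sign(Z) * Z ** 2 / _LN10_2

    scan = pd.DataFrame({
        "chrom": gm.chrom.astype(str), "pos": gm.pos, "marker": gm.marker_ids,
        "S": S, "null_mean": mean, "null_sd": sd, "Z": Z, "LOD": lod})

    regions = merge_regions(scan, gap_markers=params.gap_markers)
    return scan, regions


def merge_regions(scan: pd.DataFrame, gap_markers: int = 0) -> list[LinkedRegion]:
    """Maximal runs of Z > 0, bridging <= gap_markers undefined markers.

    A region's genomic span extends beyond its outermost positive markers to
    the midpoint toward the first contradicting (Z <= 0) marker on either
    side: undefined markers in between carry no evidence, so the region
    boundary lies somewhere in the uninformative stretch.
    """
    regions: list[LinkedRegion] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        z = sub["Z"].to_numpy()
        neg_idx = np.flatnonzero(~np.isnan(z) & (z <= 0))

        def close(run):
            if not run:
                return
            zz = z[run]
            lo, hi = pos[run[0]], pos[run[-1]] + 1
            before = neg_idx[neg_idx < run[0]]
            after = neg_idx[neg_idx > run[-1]]
            if len(before):
                lo = (pos[before[-1]] + 1 + lo) // 2
            if len(after):
                hi = (hi + pos[after[0]]) // 2
            regions.append(LinkedRegion(
                chrom=str(chrom), start=int(lo), end=int(hi),
                n_markers=len(run), max_Z=float(zz.max()),
                max_LOD=float((zz.max() ** 2) / _LN10_2)))

        run: list[int] = []
        gap = 0
        for k in range(len(z)):
            if np.isnan(z[k]):
                if run and gap < gap_markers:
                    gap += 1
                else:
                    close(run)
                    run, gap = [], 0
            elif z[k] > 0:
                run.append(k)
                gap = 0
            else:
                close(run)
                run, gap = [], 0
        close(run)
    return regions
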