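import itertools

import numpy as np
import pandas as pd
import pytest

from comphet import linkage as lk
from comphet.io_formats import GenotypeMatrix
from comphet.pedigree import Individual, Pedigree

_LN10_2 = 2 * np.log(10)


def _gm(calls, sample_ids, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_m = calls.shape[1]
    return GenotypeMatrix(sample_ids, [f"M{j}" for j in range(n_m)],
                          np.array(["1"] * n_m, dtype=object),
                          pos if pos is not None else np.arange(n_m) + 1,
                          calls)


def _halfsib_ped():
    return Pedigree([
        Individual("SIRE", sex="male"),
        Individual("D1", sex="female"), Individual("D2", sex="female"),
        Individual("C1", sire_id="SIRE", dam_id="D1", phenotype="affected"),
        Individual("C2", sire_id="SIRE", dam_id="D2", phenotype="affected")])


def _fullsib_ped():
    return Pedigree([
        Individual("SIRE", sex="male"), Individual("DAM", sex="female"),
        Individual("C1", sire_id="SIRE", dam_id="DAM", phenotype="affected"),
        Individual("C2", sire_id="SIRE", dam_id="DAM", phenotype="affected")])


def _gs_ped():
    return Pedigree([
        Individual("GS", sex="male", phantom=True),
        Individual("SIRE", sex="male"),
        Individual("D1", sire_id="GS", sex="female"),
        Individual("D2", sire_id="GS", sex="female"),
        Individual("C1", sire_id="SIRE", dam_id="D1", phenotype="affected"),
        Individual("C2", sire_id="SIRE", dam_id="D2", phenotype="affected")])


_HAPS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _brute_halfsib(s, di, ci, dj, cj):
    """Exhaustive enumeration over transmissions for one half-sib pair."""
    num = den = 0.0
    sh = _HAPS[s]
    for hi, hj, mi, mj in itertools.product((0, 1), repeat=4):
        if sh[hi] + _HAPS[di][mi] != ci or sh[hj] + _HAPS[dj][mj] != cj:
            continue
        den += 1
        num += (hi == hj)
    return None if den == 0 else num / den


def _brute_fullsib(s, d, ci, cj):
    num = den = 0.0
    sh, dh = _HAPS[s], _HAPS[d]
    for hi, mi, hj, mj in itertools.product((0, 1), repeat=4):
        if sh[hi] + dh[mi] != ci or sh[hj] + dh[mj] != cj:
            continue
        den += 1
        num += (hi == hj) + (mi == mj)
    return None if den == 0 else num / den


def _brute_grandsire(s, di, ci, dj, cj, f):
    """Exhaustive enumeration including the latent ungenotyped grandsire."""
    num = den = 0.0
    for (s1, s2, g1, g2, ui, mi, uj, mj, vi, hi, vj, hj) in itertools.product(
            (0, 1), repeat=12):
        w = 1.0
        for allele in (s1, s2, g1, g2, mi, mj):
            w *= f if allele else (1 - f)
        if s >= 0 and s1 + s2 != s:
            continue
        dam_i_pat = (g1, g2)[ui]
        dam_j_pat = (g1, g2)[uj]
        if di >= 0 and dam_i_pat + mi != di:
            continue
        if dj >= 0 and dam_j_pat + mj != dj:
            continue
        mat_i = dam_i_pat if vi == 0 else mi
        mat_j = dam_j_pat if vj == 0 else mj
        if ci >= 0 and (s1, s2)[hi] + mat_i != ci:
            continue
        if cj >= 0 and (s1, s2)[hj] + mat_j != cj:
            continue
        den += w
        num += w * ((hi == hj) + (vi == 0 and vj == 0 and ui == uj))
    return None if den == 0 else num / den


class TestEstimatorAgainstBruteForce:
    def test_halfsib_pairs_match_enumeration(self):
        ped = _halfsib_ped()
        pairs = lk.affected_pairs(ped, ["C1", "C2"], genotyped={"SIRE", "D1", "D2",
                                                                "C1", "C2"})
        assert pairs[0].kind == "HS"
        for s, di, ci, dj, cj in itertools.product((0, 1, 2), repeat=5):
            genos = {"SIRE": np.array([s], np.int8), "D1": np.array([di], np.int8),
                     "D2": np.array([dj], np.int8), "C1": np.array([ci], np.int8),
                     "C2": np.array([cj], np.int8)}
            S, _ = lk._sharing_from_genotypes(genos, pairs, np.array([0.4]))
            expect = _brute_halfsib(s, di, ci, dj, cj)
            if expect is None:
                expect = 0.5  # Mendelian-inconsistent -> prior
            assert S[0] == pytest.approx(expect / 2)

    def test_fullsib_pairs_match_enumeration(self):
        ped = _fullsib_ped()
        pairs = lk.affected_pairs(ped, ["C1", "C2"])
        assert pairs[0].kind == "FS"
        for s, d, ci, cj in itertools.product((0, 1, 2), repeat=4):
            genos = {"SIRE": np.array([s], np.int8), "DAM": np.array([d], np.int8),
                     "C1": np.array([ci], np.int8), "C2": np.array([cj], np.int8)}
            S, _ = lk._sharing_from_genotypes(genos, pairs, np.array([0.4]))
            expect = _brute_fullsib(s, d, ci, cj)
            if expect is None:
                expect = 1.0
            assert S[0] == pytest.approx(expect / 2)

    @pytest.mark.parametrize("f", [0.15, 0.35, 0.5])
    def test_grandsire_pairs_match_enumeration(self, f):
        ped = _gs_ped()
        genotyped = {"SIRE", "D1", "D2", "C1", "C2"}
        pairs = lk.affected_pairs(ped, ["C1", "C2"], genotyped)
        assert pairs[0].kind == "HS_GS"
        rng = np.random.default_rng(0)
        for _ in range(60):
            s, di, ci, dj, cj = rng.integers(-1, 3, size=5)
            genos = {"SIRE": np.array([s], np.int8), "D1": np.array([di], np.int8),
                     "D2": np.array([dj], np.int8), "C1": np.array([ci], np.int8),
                     "C2": np.array([cj], np.int8)}
            S, _ = lk._sharing_from_genotypes(genos, pairs, np.array([f]))
            expect = _brute_grandsire(int(s), int(di), int(ci), int(dj),
                                      int(cj), f)
            if expect is None:
                expect = 2 * lk._GS_PRIOR
            assert S[0] == pytest.approx(expect / 2, abs=1e-12)


class TestStatisticExamples:
    def test_fully_informative_fullsib_pair_shares_one(self):
        # sire and dam het, both children homozygous reference: both paternal
        # and maternal transmissions are traceable and identical
        ped = _fullsib_ped()
        gm = _gm([[1], [1], [0], [0]], ["SIRE", "DAM", "C1", "C2"])
        S = lk.pairwise_sharing_statistic(gm, ped, 0, ["C1", "C2"], freq=0.5)
        assert S == pytest.approx(1.0)

    def test_identically_homozygous_marker_is_undefined(self):
        ped = _halfsib_ped()
        gm = _gm([[2], [2], [2], [2], [2]], ["SIRE", "D1", "D2", "C1", "C2"])
        assert np.isnan(lk.pairwise_sharing_statistic(gm, ped, 0,
                                                      ["C1", "C2"], freq=0.5))

    def test_requires_two_affecteds(self):
        ped = _halfsib_ped()
        gm = _gm([[1]], ["C1"])
        with pytest.raises(ValueError):
            lk.pairwise_sharing_statistic(gm, ped, 0, ["C1"])

    def test_matches_transmitted_label_oracle_on_informative_markers(self):
        """Five half-sib lambs, genotypes built from known transmissions:
        where the estimator is determinate it must equal the true IBD count."""
        rng = np.random.default_rng(42)
        n_aff = 5
        ids = ["SIRE"] + [f"D{k}" for k in range(n_aff)] + \
            [f"C{k}" for k in range(n_aff)]
        inds = [Individual("SIRE", sex="male")]
        inds += [Individual(f"D{k}", sex="female") for k in range(n_aff)]
        inds += [Individual(f"C{k}", sire_id="SIRE", dam_id=f"D{k}",
                            phenotype="affected") for k in range(n_aff)]
        ped = Pedigree(inds)
        affect = [f"C{k}" for k in range(n_aff)]
        for _ in range(200):
            sire_h = (0, 1)  # heterozygous, haplotypes labelled by allele
            truth_h = rng.integers(0, 2, n_aff)       # transmitted sire hap
            dam_gt = [0, 2] * 3                       # homozygous dams
            calls = {"SIRE": 1}
            for k in range(n_aff):
                calls[f"D{k}"] = dam_gt[k]
                calls[f"C{k}"] = sire_h[truth_h[k]] + dam_gt[k] // 2
            gm = _gm(np.array([[calls[i]] for i in ids]), ids)
            S = lk.pairwise_sharing_statistic(gm, ped, 0, affect, freq=0.5)
            expected = sum((truth_h[a] == truth_h[b]) / 2
                           for a in range(n_aff) for b in range(a + 1, n_aff))
            assert S == pytest.approx(expected)


class TestGeneDropNull:
    def test_unrelated_pair_shares_nothing(self):
        ped = Pedigree([Individual("A", phenotype="affected"),
                        Individual("B", phenotype="affected")])
        mean, sd = lk.gene_drop_null(ped, np.array([0.5]), ["A", "B"],
                                     n_reps=200, seed=1)
        assert mean[0] == 0.0
        assert sd[0] == 0.0

    def test_fullsib_null_mean_is_one_shared_allele(self):
        ped = _fullsib_ped()
        mean, sd = lk.gene_drop_null(ped, np.array([0.5]), ["C1", "C2"],
                                     n_reps=4000, seed=3)
        # E[IBD] = 1 of 2 alleles -> 0.5 on the normalised scale
        assert mean[0] == pytest.approx(0.5, abs=3 * sd[0] / np.sqrt(4000))

    def test_two_seeds_agree_within_monte_carlo_error(self, flock):
        freqs = np.array([0.3])
        m1, s1 = lk.gene_drop_null(flock.pedigree, freqs, flock.affected,
                                   n_reps=1000, seed=1,
                                   genotyped=set(flock.gm.sample_ids))
        m2, s2 = lk.gene_drop_null(flock.pedigree, freqs, flock.affected,
                                   n_reps=1000, seed=2,
                                   genotyped=set(flock.gm.sample_ids))
        mc_se = np.sqrt(s1[0] ** 2 + s2[0] ** 2) / np.sqrt(1000)
        assert abs(m1[0] - m2[0]) <= 3 * mc_se

    def test_small_rep_count_warns(self):
        ped = _fullsib_ped()
        with pytest.warns(UserWarning, match="unstable"):
            lk.gene_drop_null(ped, np.array([0.5]), ["C1", "C2"],
                              n_reps=50, seed=1)

    def test_seed_is_mandatory(self):
        ped = _fullsib_ped()
        with pytest.raises(ValueError, match="seed"):
            lk.gene_drop_null(ped, np.array([0.5]), ["C1", "C2"], n_reps=200)


class TestScanAndRegions:
    def test_lod_is_z_squared_over_2ln10(self, flock):
        scan, _ = lk.scan_and_merge(flock.gm, flock.pedigree, flock.affected,
                                    lk.LinkageParams(n_reps=300, seed=5))
        defined = scan.dropna(subset=["Z"])
        assert np.allclose(defined["LOD"],
                           np.sign(defined["Z"]) * defined["Z"] ** 2 / _LN10_2)
        assert (defined["null_sd"] > 0).all()

    def test_allele_relabelling_leaves_z_unchanged(self, flock):
        params = lk.LinkageParams(n_reps=300, seed=9)
        scan1, _ = lk.scan_and_merge(flock.gm, flock.pedigree, flock.affected,
                                     params)
        flipped = flock.gm.calls.copy()
        flipped[flipped >= 0] = 2 - flipped[flipped >= 0]
        gm2 = GenotypeMatrix(flock.gm.sample_ids, flock.gm.marker_ids,
                             flock.gm.chrom, flock.gm.pos, flipped)
        scan2, _ = lk.scan_and_merge(gm2, flock.pedigree, flock.affected,
                                     params)
        z1, z2 = scan1["Z"].to_numpy(), scan2["Z"].to_numpy()
        assert np.array_equal(np.isnan(z1), np.isnan(z2))
        assert np.array_equal(z1[~np.isnan(z1)], z2[~np.isnan(z2)])

    def test_scan_recovers_causal_region(self, flock):
        scan, regions = lk.scan_and_merge(flock.gm, flock.pedigree,
                                          flock.affected,
                                          lk.LinkageParams(seed=1001))
        chrom, pos = flock.truth.causal_positions[0]
        assert any(r.contains(chrom, pos) for r in regions)

    def test_region_merging_rules(self):
        z = [np.nan, 1.0, np.nan, 2.0, -1.0, 0.5, np.nan, np.nan, 1.5, np.nan]
        scan = pd.DataFrame({
            "chrom": ["1"] * 10, "pos": np.arange(10) * 100 + 100,
            "Z": z})
        # gap 0: the undefined marker splits the first run
        r0 = lk.merge_regions(scan, gap_markers=0)
        assert [(r.n_markers) for r in r0] == [1, 1, 1, 1]
        # gap 1: bridges single undefined markers, not the double gap
        r1 = lk.merge_regions(scan, gap_markers=1)
        assert [r.n_markers for r in r1] == [2, 1, 1]
        assert r1[0].max_Z == 2.0
        # spans extend to the midpoint toward the contradicting marker
        first = r1[0]
        assert first.start <= 200
        assert first.end == (401 + 500) // 2

    def test_all_uninformative_scan_has_no_regions(self):
        scan = pd.DataFrame({"chrom": ["1"] * 5, "pos": np.arange(5) + 1,
                             "Z": [np.nan] * 5})
        assert lk.merge_regions(scan, gap_markers=2) == []
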