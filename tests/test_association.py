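"""Genotype QC, residualization, per-SNP scan, clumping, GRM utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import asymlat as al
from asymlat.association import hwe_pvalues
from conftest import run_scan


def make_matrix(dosages, positions=None, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    chroms = chroms if chroms is not None else ["1"] * m
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return al.GenotypeMatrix(
        subject_ids=np.array([f"i{i}" for i in range(n)]), snps=snps, dosages=dosages
    )


class TestGenotypeQc:
    def test_maf_from_counts(self):
        G = make_matrix(np.array([[0.0], [1.0], [2.0], [2.0]]))
        assert G.maf()[0] == pytest.approx(0.375)
        assert al.qc_genotypes(G, maf_min=0.01).n_snps == 1

    def test_hwe_exact_proportions(self):
        d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None]
        assert hwe_pvalues(make_matrix(d))[0] == pytest.approx(1.0)

    def test_hwe_chi2_tail(self):
        d = np.repeat([0.0, 1.0, 2.0], [30, 40, 30])[:, None]
        # chi-square = 4 on 1 df
        assert hwe_pvalues(make_matrix(d))[0] == pytest.approx(
            stats.chi2.sf(4.0, 1), abs=1e-10
        )
        assert al.qc_genotypes(make_matrix(d), hwe_p_min=1e-6).n_snps == 1

    def test_missingness_filter(self):
        d = np.full((100, 1), 1.0)
        d[:10, 0] = np.nan
        d[10:60, 0] = 0.0
        assert al.qc_genotypes(make_matrix(d), miss_max=0.05).n_snps == 0

    def test_idempotence(self, small_genotypes):
        cfg_missing = al.GeneratorConfig(n_subjects=400, n_snps=300, missing_rate=0.08, seed=41, maf_range=(0.01, 0.5))
        G = al.gen_genotypes(cfg_missing)
        once = al.qc_genotypes(G)
        twice = al.qc_genotypes(once)
        np.testing.assert_array_equal(
            np.nan_to_num(once.dosages, nan=-1), np.nan_to_num(twice.dosages, nan=-1)
        )


class TestResidualize:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"age": rng.uniform(40, 69, 100), "sex": rng.integers(0, 2, 100)})
        y = 2.0 * cov["age"].to_numpy() + 1.0
        resid = al.residualize(y, cov)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_orthogonality(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("abcd"))
        y = rng.standard_normal(300)
        resid = al.residualize(y, cov)
        for col in cov.columns:
            assert abs(resid @ cov[col].to_numpy()) < 1e-8

    def test_independent_covariates_keep_variance(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame(rng.standard_normal((5000, 3)), columns=list("abc"))
        y = rng.standard_normal(5000)
        resid = al.residualize(y, cov)
        assert resid.var() == pytest.approx(y.var(), rel=0.01)

    def test_missing_propagates(self):
        cov = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        y = np.array([1.0, np.nan, 3.0, 5.0])
        resid = al.residualize(y, cov)
        assert np.isnan(resid[1]) and not np.isnan(resid[[0, 2, 3]]).any()

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(50)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            al.residualize(rng.standard_normal(50), cov)


class TestAssocScan:
    def test_perfect_linear_fit(self):
        G = make_matrix(np.array([[0, 1, 2, 0, 1, 2]], dtype=float).T)
        res = al.assoc_scan(np.array([0.0, 1, 2, 0, 1, 2]), G)
        assert res.table["beta"][0] == pytest.approx(1.0, abs=1e-6)
        assert res.table["p"][0] < 1e-10

    def test_hand_ols(self):
        G = make_matrix(np.array([[0, 1, 2, 1]], dtype=float).T)
        res = al.assoc_scan(np.array([1.0, 2.0, 3.0, 1.0]), G)
        assert res.table["beta"][0] == pytest.approx(1.0, abs=1e-6)

    def test_monomorphic_snp_missing(self):
        G = make_matrix(np.column_stack([np.ones(10), np.arange(10) % 3]).astype(float))
        res = al.assoc_scan(np.random.default_rng(0).standard_normal(10), G)
        assert np.isnan(res.table["p"][0]) and not np.isnan(res.table["p"][1])

    def test_pairwise_complete_matches_manual(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(200, 1)).astype(float)
        d[rng.random(200) < 0.2, 0] = np.nan
        y = rng.standard_normal(200)
        res = al.assoc_scan(y, make_matrix(d))
        ok = ~np.isnan(d[:, 0])
        slope, _, _, p, _ = stats.linregress(d[ok, 0], y[ok])
        assert res.table["beta"][0] == pytest.approx(slope, rel=1e-4)
        assert res.table["p"][0] == pytest.approx(p, rel=1e-3)
        assert res.table["n_used"][0] == ok.sum()

    def test_type_one_error_calibrated(self, null_cohort):
        cfg, G, traits_tab, cov = null_cohort
        res = run_scan(G, traits_tab, cov)
        frac = (res.table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.025)


class TestInflationFactor:
    def test_flat_half(self):
        assert al.inflation_factor([0.5] * 7) == pytest.approx(1.0)

    def test_uniform_near_one(self):
        rng = np.random.default_rng(6)
        lam = al.inflation_factor(rng.uniform(size=100_000))
        assert 0.98 <= lam <= 1.02

    def test_deflated_p_inflates_lambda(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=10_000)
        assert al.inflation_factor(p / 2) > al.inflation_factor(p)


class TestLdR2:
    def test_identical_and_mirrored(self):
        d = np.random.default_rng(8).integers(0, 3, size=(50, 1)).astype(float)
        G = make_matrix(np.column_stack([d, d, 2 - d]))
        assert al.ld_r2(G, "s0", "s1") == pytest.approx(1.0)
        assert al.ld_r2(G, "s0", "s2") == pytest.approx(1.0)

    def test_hand_value(self):
        G = make_matrix(np.column_stack([[0, 1, 2, 0], [1, 1, 1, 2]]).astype(float))
        assert al.ld_r2(G, "s0", "s1") == pytest.approx(0.272727, abs=1e-4)

    def test_monomorphic_undefined(self):
        G = make_matrix(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]).astype(float))
        assert np.isnan(al.ld_r2(G, "s0", "s1"))


def brute_force_clump(table, G, p1, p2, r2, kb):
    """Independent reimplementation that re-scans all pairs each round."""
    t = table.copy()
    assigned = set()
    clumps = []
    while True:
        cand = t[(t["p"] < p1) & ~t["snp_id"].isin(assigned)]
        if cand.empty:
            break
        cand = cand.sort_values(["p", "chrom", "pos"], kind="mergesort")
        idx = cand.iloc[0]
        assigned.add(idx["snp_id"])
        members = []
        for _, row in t.iterrows():
            if row["snp_id"] in assigned or not (row["p"] < p2):
                continue
            if row["chrom"] != idx["chrom"] or abs(row["pos"] - idx["pos"]) > kb * 1000:
                continue
            rr = al.ld_r2(G, idx["snp_id"], row["snp_id"])
            if not np.isnan(rr) and rr >= r2:
                members.append(row["snp_id"])
                assigned.add(row["snp_id"])
        clumps.append((idx["snp_id"], sorted(members)))
    return clumps


class TestClump:
    def test_hand_trace(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, 400).astype(float)
        s2 = base.copy()
        flip = rng.random(400) < 0.05  # keeps r2 well above 0.5
        s2[flip] = rng.integers(0, 3, flip.sum())
        s3 = rng.integers(0, 3, 400).astype(float)  # unlinked
        G = make_matrix(
            np.column_stack([base, s2, s3]), positions=[100, 150_000, 400_000]
        )
        assert al.ld_r2(G, "s0", "s1") >= 0.5
        assert al.ld_r2(G, "s0", "s2") < 0.5
        table = pd.DataFrame(
            {
                "snp_id": ["s0", "s1", "s2"],
                "chrom": "1",
                "pos": [100, 150_000, 400_000],
                "a1": "G", "a2": "A", "maf": 0.3, "n_used": 400,
                "beta": 0.1, "se": 0.01,
                "p": [1e-10, 1e-9, 9e-9],
            }
        )
        clumps = al.clump(al.AssocResultSet(table), G)
        assert [c.index_snp for c in clumps] == ["s0", "s2"]
        assert clumps[0].members == ["s1"]

    def test_no_significant_snps(self, small_genotypes):
        res = al.assoc_scan(
            np.random.default_rng(0).standard_normal(small_genotypes.n_subjects),
            small_genotypes,
        )
        res.table["p"] = np.clip(res.table["p"], 0.01, 1.0)
        assert al.clump(res, small_genotypes) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 50))
        cfg = al.GeneratorConfig(
            n_subjects=120, n_snps=m, seed=seed, ld_block_size=5,
            n_chromosomes=2, snp_spacing=int(rng.integers(5_000, 200_000)),
        )
        G = al.gen_genotypes(cfg)
        p = 10.0 ** rng.uniform(-12, 0, m)
        table = G.snps.copy()
        table["a1"], table["a2"] = table.pop("alt"), table.pop("ref")
        table["maf"], table["n_used"] = 0.3, 120
        table["beta"], table["se"], table["p"] = 0.1, 0.01, p
        res = al.AssocResultSet(table)
        p1 = 10.0 ** rng.uniform(-8, -2)
        ours = [(c.index_snp, sorted(c.members)) for c in al.clump(res, G, p1=p1, p2=p1, r2=0.4, kb=100)]
        theirs = brute_force_clump(table, G, p1=p1, p2=p1, r2=0.4, kb=100)
        assert ours == theirs


class TestGrm:
    def test_single_snp_hand_values(self):
        G = make_matrix(np.array([[0.0], [2.0]]))
        grm = al.compute_grm(G)
        np.testing.assert_allclose(grm.values, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-6)

    def test_duplicate_subjects_detected(self):
        cfg = al.GeneratorConfig(n_subjects=50, n_snps=2000, seed=12, ld_block_size=1)
        G = al.gen_genotypes(cfg)
        d = np.vstack([G.dosages, G.dosages[:1]])  # duplicate first subject
        G2 = al.GenotypeMatrix(
            subject_ids=np.append(G.subject_ids, "dup"), snps=G.snps, dosages=d
        )
        grm = al.compute_grm(G2)
        assert grm.values[0, -1] == pytest.approx(grm.values[0, 0], abs=0.05)

    def test_sparsify_and_prune(self):
        n = 120
        v = np.eye(n)
        v[0, 1:103] = v[1:103, 0] = 0.06  # subject 0 has 102 relatives
        grm = al.RelatednessMatrix(np.array([f"i{i}" for i in range(n)]), v)
        sparse = al.sparsify_grm(grm, cutoff=0.05)
        assert (sparse.values[0] != 0).sum() == 103  # incl. diagonal
        removed = al.prune_related(sparse, max_relatives=100)
        assert removed == ["i0"]

    def test_small_entries_zeroed(self):
        v = np.array([[1.0, 0.01], [0.01, 1.0]])
        sparse = al.sparsify_grm(al.RelatednessMatrix(np.array(["a", "b"]), v))
        assert sparse.values[0, 1] == 0.0

    def test_no_polymorphic_snps_errors(self):
        G = make_matrix(np.ones((4, 2)))
        with pytest.raises(ValueError, match="polymorphic"):
            al.compute_grm(G)
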