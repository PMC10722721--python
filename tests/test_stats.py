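"""Association statistics: FST oracle, regressions, tests and categories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import clinemap as cm
from clinemap.genotypes import MISSING, GenotypeMatrix
from clinemap.stats import variant_type


def _matrix_from_pops(pop_genos):
    """pop_genos: dict pop -> (n_samples, n_loci) genotype array."""
    ids, rows, labels = [], [], {}
    for pop, G in pop_genos.items():
        for i, row in enumerate(np.asarray(G, dtype=np.int8)):
            sid = f"{pop}_{i}"
            ids.append(sid)
            rows.append(row)
            labels[sid] = pop
    G = np.stack(rows)
    L = G.shape[1]
    loci = pd.DataFrame({"chrom": ["1"] * L, "pos": np.arange(L) + 1,
                         "ref": ["A"] * L, "alt": ["G"] * L,
                         "id": [f"v{i}" for i in range(L)],
                         "focal_is_alt": True})
    return GenotypeMatrix(ids, loci, G), labels


def _wc_theta_oracle(genos_by_pop):
    """Weir & Cockerham (1984) theta, independently transcribed per locus."""
    pops = [np.asarray(g, dtype=float) for g in genos_by_pop
            if len(g) and not all(x == MISSING for x in g)]
    r = len(pops)
    n = [sum(1 for x in g if x != MISSING) for g in pops]
    p = [sum(x for x in g if x != MISSING) / (2 * ni)
         for g, ni in zip(pops, n)]
    ho = [sum(1 for x in g if x == 1) / ni for g, ni in zip(pops, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar)**2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, ho)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestWeirFst:
    def test_identical_hwe_populations_clamp_to_zero(self):
        # both pops with p=0.5 and exact HWE genotype counts
        col = [0, 1, 1, 2] * 3
        gm, labels = _matrix_from_pops({
            "A": np.array(col)[:, None], "B": np.array(col)[:, None]})
        out = cm.weir_fst_multipop(gm, labels)
        assert out["fst_raw"].iloc[0] <= 0
        assert out["fst_clamped"].iloc[0] == 0.0

    def test_fixed_difference_gives_one(self):
        gm, labels = _matrix_from_pops({
            "A": np.full((10, 1), 2), "B": np.zeros((10, 1))})
        out = cm.weir_fst_multipop(gm, labels)
        assert out["fst_raw"].iloc[0] == pytest.approx(1.0)

    def test_matches_independent_oracle_with_missing_data(self):
        rng = np.random.default_rng(0)
        for trial in range(15):
            r = rng.integers(2, 5)
            genos = {}
            for k in range(r):
                g = rng.integers(0, 3, size=(rng.integers(4, 12), 8))
                g[rng.uniform(size=g.shape) < 0.1] = MISSING
                genos[f"P{k}"] = g
            gm, labels = _matrix_from_pops(genos)
            out = cm.weir_fst_multipop(gm, labels)
            for j in range(8):
                cols = [genos[f"P{k}"][:, j] for k in range(r)]
                expect = _wc_theta_oracle(cols)
                got = out["fst_raw"].iloc[j]
                if np.isnan(expect) or np.isnan(got):
                    assert np.isnan(expect) == np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        genos = {p: rng.integers(0, 3, size=(6, 5)) for p in "ABC"}
        gm, labels = _matrix_from_pops(genos)
        out1 = cm.weir_fst_multipop(gm, labels)
        renamed = {s: {"A": "C", "B": "A", "C": "B"}[l]
                   for s, l in labels.items()}
        out2 = cm.weir_fst_multipop(gm, renamed)
        assert np.allclose(out1["fst_raw"], out2["fst_raw"], equal_nan=True)

    def test_requires_two_populations(self):
        gm, labels = _matrix_from_pops({"A": np.zeros((4, 2))})
        with pytest.raises(ValueError):
            cm.weir_fst_multipop(gm, labels)


class TestFstGroupAnova:
    def test_monotone_construction_gives_increasing_means(self):
        rng = np.random.default_rng(2)
        fst = rng.uniform(0, 0.6, size=4000)
        lnv = 2.0 * fst + rng.normal(0, 0.1, size=4000)
        out = cm.fst_group_anova(fst, lnv)
        assert (np.diff(out["group_means"]) > 0).all()
        assert out["p"] < 1e-10
        assert out["pearson_r"] > 0.9

    def test_two_bin_anova_equals_squared_t(self):
        rng = np.random.default_rng(3)
        fst = np.r_[rng.uniform(0.0, 0.2, 200), rng.uniform(0.2, 0.4, 200)]
        lnv = rng.normal(size=400) + (fst > 0.2) * 0.3
        out = cm.fst_group_anova(fst, lnv, bin_edges=[0.0, 0.2, 0.4])
        a, b = lnv[fst <= 0.2], lnv[fst > 0.2]
        t, _ = sps.ttest_ind(a, b)
        assert out["F"] == pytest.approx(t**2, rel=1e-9)

    def test_empty_bins_dropped_and_single_bin_rejected(self):
        rng = np.random.default_rng(4)
        # two occupied default bins: empty upper bins dropped, ANOVA runs
        fst = rng.uniform(0, 0.1, 100)
        out = cm.fst_group_anova(fst, rng.normal(size=100))
        assert len(out["group_means"]) == 2
        # a single occupied bin cannot support an ANOVA
        with pytest.raises(ValueError):
            cm.fst_group_anova(rng.uniform(0, 0.04, 100),
                               rng.normal(size=100))


class TestEffectRegression:
    def test_category_shift_recovered(self):
        rng = np.random.default_rng(5)
        cats = np.repeat(["intron_variant", "missense_variant",
                          "synonymous_variant"], 1500)
        lnv = rng.normal(0, 0.3, size=4500)
        lnv[cats == "missense_variant"] += 1.0
        out = cm.effect_regression(lnv, cats, min_count=1000)
        per = out["per_category"].set_index("category")["estimate"]
        assert per["missense_variant"] - per["intron_variant"] == \
            pytest.approx(1.0, abs=0.05)
        assert out["p"] < 1e-10

    def test_equal_means_give_large_p(self):
        rng = np.random.default_rng(6)
        cats = np.repeat(["a", "b"], 1200)
        out = cm.effect_regression(rng.normal(size=2400), cats,
                                   min_count=1000)
        assert out["p"] > 0.01

    def test_underrepresented_category_removed(self):
        rng = np.random.default_rng(7)
        cats = np.array(["big1"] * 1500 + ["big2"] * 1200 + ["small"] * 999)
        out = cm.effect_regression(rng.normal(size=len(cats)), cats,
                                   min_count=1000)
        kept = set(out["per_category"]["category"])
        assert kept == {"big1", "big2"}

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            cm.effect_regression(np.zeros(2000), ["x"] * 2000)


class TestSnpIndel:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "SNP"), ("A", "AT", "indel"), ("ATG", "A", "indel"),
        ("AT", "GC", "MNP"),
    ])
    def test_length_rule(self, ref, alt, expected):
        assert variant_type(ref, alt) == expected

    def test_shifted_indels_detected(self):
        rng = np.random.default_rng(8)
        n = 600
        ref = np.array(["A"] * n)
        alt = np.array(["G"] * n, dtype=object)
        alt[:100] = "GT"
        lnv = rng.normal(0, 0.5, size=n)
        lnv[:100] += 0.8
        out = cm.snp_indel_test(lnv, ref, alt)
        assert out["indel_mean"] > out["snp_mean"]
        assert out["p"] < 1e-6
        assert out["n_indel"] == 100 and out["n_snp"] == 500

    def test_absent_type_rejected(self):
        with pytest.raises(ValueError):
            cm.snp_indel_test(np.zeros(5), ["A"] * 5, ["G"] * 5)


class TestClassifyRecomb:
    def _map(self, s1, s2, chrom="1"):
        n = len(s1)
        return pd.DataFrame({
            "chrom": [chrom] * n,
            "bin_start": np.arange(n) * 1_000_000,
            "bin_end": (np.arange(n) + 1) * 1_000_000,
            "crossovers_sire1": s1, "crossovers_sire2": s2})

    def test_three_zero_bins_in_either_sire_are_coldspots(self):
        m = self._map([5, 0, 0, 0, 6, 7, 8], [4, 5, 6, 7, 8, 9, 10])
        out = cm.classify_recomb(m)["bins"]
        assert out["category"].tolist()[1:4] == ["coldspot"] * 3

    def test_two_zero_bins_are_not(self):
        m = self._map([5, 0, 0, 6, 7, 8, 9], [4, 5, 6, 7, 8, 9, 10])
        out = cm.classify_recomb(m)["bins"]
        assert "coldspot" not in set(out["category"])

    def test_hotspot_requires_both_sires(self):
        s = [8] * 20
        m1 = self._map(s[:-1] + [60], s[:-1] + [60])
        m2 = self._map(s[:-1] + [60], s)
        assert cm.classify_recomb(m1)["bins"]["category"].iloc[-1] == "hotspot"
        assert cm.classify_recomb(m2)["bins"]["category"].iloc[-1] == "other"

    def test_explicit_hotspot_list_overrides_derivation(self):
        m = self._map([8] * 6, [8] * 6)
        hs = pd.DataFrame({"chrom": ["1"], "bin_start": [2_000_000]})
        out = cm.classify_recomb(m, hotspot_list=hs)["bins"]
        assert out["category"].iloc[2] == "hotspot"

    def test_variant_assignment_and_uncovered_default(self):
        m = self._map([5, 0, 0, 0, 6], [4, 5, 6, 7, 8])
        variants = pd.DataFrame({"chrom": ["1", "1", "9"],
                                 "pos": [1_500_000, 4_500_000, 100]})
        out = cm.classify_recomb(m, variants=variants)
        assert out["variant_category"].tolist() == ["coldspot", "other",
                                                    "other"]

    def test_malformed_map_rejected(self):
        with pytest.raises(ValueError):
            cm.classify_recomb(pd.DataFrame({"chrom": ["1"]}))


class TestRecombRegression:
    def test_raised_coldspot_detected(self):
        rng = np.random.default_rng(9)
        cats = np.array(["other"] * 500 + ["coldspot"] * 120
                        + ["hotspot"] * 80)
        y = rng.normal(size=len(cats))
        y[cats == "coldspot"] += 0.7
        out = cm.recomb_category_regression(y, cats)
        tk = out["tukey"]
        row = tk[(tk.group1 == "coldspot") & (tk.group2 == "other")]
        assert bool(row["reject"].iloc[0])
        assert out["p"] < 1e-6

    def test_equal_means_all_contrasts_include_zero(self):
        rng = np.random.default_rng(10)
        cats = np.array(["other", "coldspot", "hotspot"] * 200)
        out = cm.recomb_category_regression(rng.normal(size=600), cats)
        assert not out["tukey"]["reject"].astype(bool).any()

    def test_two_categories_reduce_to_t_test(self):
        rng = np.random.default_rng(11)
        cats = np.array(["a"] * 150 + ["b"] * 150)
        y = rng.normal(size=300) + (cats == "b") * 0.2
        out = cm.recomb_category_regression(y, cats)
        t, p = sps.ttest_ind(y[cats == "a"], y[cats == "b"])
        assert out["F"] == pytest.approx(t**2, rel=1e-9)
        assert out["p"] == pytest.approx(p, rel=1e-9)


class TestCentreChisq:
    def test_proportional_rows_give_zero(self):
        out = cm.centre_class_chisq({"a": 10, "b": 20, "c": 10},
                                    {"a": 100, "b": 200, "c": 100})
        assert out["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert out["df"] == 2

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            t = rng.integers(5, 500, size=(2, 3)).astype(float)
            out = cm.centre_class_chisq(
                dict(zip("abc", t[0])), dict(zip("abc", t[1])))
            # direct Pearson formula
            rows = t.sum(axis=1, keepdims=True)
            cols = t.sum(axis=0, keepdims=True)
            expect = ((t - rows * cols / t.sum())**2
                      / (rows * cols / t.sum())).sum()
            assert out["chi2"] == pytest.approx(expect, abs=1e-10)

    def test_complement_background(self):
        scv = {"a": 10, "b": 20, "c": 10}
        allv = {"a": 50, "b": 200, "c": 100}
        out_all = cm.centre_class_chisq(scv, allv, background="all")
        out_c = cm.centre_class_chisq(scv, allv, background="complement")
        assert out_all["chi2"] > 0 and out_c["chi2"] > 0
        assert out_c["chi2"] != pytest.approx(out_all["chi2"])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            cm.centre_class_chisq({"a": 0, "b": 5, "c": 5},
                                  {"a": 0, "b": 50, "c": 50})


class TestCorrelate:
    def test_exact_cases(self):
        x = np.arange(10.0)
        assert cm.correlate(x, x) == pytest.approx(1.0)
        assert cm.correlate(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_with_nans(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        y = 0.4 * x + rng.normal(size=100)
        x[::9] = np.nan
        ok = np.isfinite(x)
        expect = (np.mean((x[ok] - x[ok].mean()) * (y[ok] - y[ok].mean()))
                  / (x[ok].std() * y[ok].std()))
        assert cm.correlate(x, y) == pytest.approx(expect, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            cm.correlate([1, 2], [1, 2])
        with pytest.raises(ValueError):
            cm.correlate([1, 1, 1, 1], [1, 2, 3, 4])
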