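"""Cline function identities, WAIC oracle checks and posterior correctness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import clinemap as cm
from clinemap.cline import ClineFitTable, compute_waic
from clinemap.genotypes import GenotypeMatrix, PopulationAssignment
from clinemap.prep import SourceFreqs

from conftest import diagnostic_freqs


class TestClineFunction:
    def test_identity_cline(self):
        h = np.linspace(0, 1, 21)
        assert np.allclose(cm.cline_function(h, 1.0, 0.5), h)

    def test_half_frequency_at_centre(self):
        for v in (0.3, 1.0, 4.0, 25.0):
            for c in (0.1, 0.5, 0.83):
                assert cm.cline_function(c, v, c) == pytest.approx(0.5)

    def test_numeric_example_steep_cline(self):
        # logistic(10 * ln(0.7/0.3)) = 0.999790...
        assert cm.cline_function(0.7, 10.0, 0.5) == pytest.approx(
            expit(10 * (logit(0.7) - logit(0.5))), abs=1e-12)
        assert cm.cline_function(0.7, 10.0, 0.5) == pytest.approx(0.99979,
                                                                  abs=5e-6)

    def test_exact_limits(self):
        assert cm.cline_function(0.0, 3.0, 0.4) == 0.0
        assert cm.cline_function(1.0, 3.0, 0.4) == 1.0

    def test_monotone_and_reflection_symmetry(self):
        h = np.linspace(0.01, 0.99, 50)
        for v, c in ((0.5, 0.3), (2.0, 0.5), (8.0, 0.7)):
            phi = cm.cline_function(h, v, c)
            assert (np.diff(phi) > 0).all()
            refl = cm.cline_function(1 - h, v, 1 - c)
            assert np.allclose(refl, 1 - phi, atol=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            cm.cline_function(0.5, -1.0, 0.5)
        with pytest.raises(ValueError):
            cm.cline_function(0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            cm.cline_function(1.5, 1.0, 0.5)


def _waic_oracle(ll):
    """Direct-formula WAIC, coded independently of the implementation."""
    n, S = len(ll), len(ll[0])
    lppd = 0.0
    p = 0.0
    for row in ll:
        m = max(row)
        lppd += m + math.log(sum(math.exp(x - m) for x in row) / S)
        mean = sum(row) / S
        p += sum((x - mean) ** 2 for x in row) / (S - 1)
    return -2.0 * (lppd - p)


class TestWaic:
    def test_constant_draws(self):
        ll = np.full((4, 10), -1.3)
        res = compute_waic(ll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2 * 4 * -1.3)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ll = -rng.exponential(1.0, size=(rng.integers(2, 8),
                                             rng.integers(2, 9)))
            res = compute_waic(ll)
            assert res.waic == pytest.approx(_waic_oracle(ll.tolist()),
                                             abs=1e-12)

    def test_duplicate_row_adds_its_contribution(self):
        rng = np.random.default_rng(1)
        ll = -rng.exponential(1.0, size=(3, 5))
        base = compute_waic(ll)
        dup = compute_waic(np.vstack([ll, ll[[0]]]))
        single = compute_waic(ll[[0]].repeat(2, axis=0)).waic / 2
        assert dup.waic == pytest.approx(base.waic + single, abs=1e-10)

    def test_weights_equal_duplication(self):
        rng = np.random.default_rng(2)
        ll = -rng.exponential(1.0, size=(3, 6))
        w = np.array([2, 1, 3])
        expanded = np.repeat(ll, w, axis=0)
        assert compute_waic(ll, weights=w).waic == pytest.approx(
            compute_waic(expanded).waic, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            compute_waic(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            compute_waic(np.array([[0.0, -np.inf]]))


def _fake_fit(waics, n_obs=10):
    tbl = pd.DataFrame({
        "chrom": ["1"] * len(waics), "pos": np.arange(len(waics)) + 1,
        "ref": "A", "alt": "G", "waic": waics, "n_obs": n_obs,
        "lnv_mean": 0.0})
    return ClineFitTable(tbl, nitt=10, burnin=5, seed=0, fix_v=False)


class TestCompareModels:
    def test_sign_convention(self):
        m = cm.compare_models(_fake_fit([100.0]), _fake_fit([120.0]))
        assert m["delta_waic"].iloc[0] == pytest.approx(-20.0)

    def test_identical_fits_give_zero(self):
        m = cm.compare_models(_fake_fit([55.0, 70.0]), _fake_fit([55.0, 70.0]))
        assert np.allclose(m["delta_waic"], 0.0)

    def test_mismatched_observations_rejected(self):
        with pytest.raises(ValueError):
            cm.compare_models(_fake_fit([1.0], n_obs=10),
                              _fake_fit([1.0], n_obs=12))


def _one_locus_data(seed=0, n_test=20, p0=0.05, p1=0.95):
    rng = np.random.default_rng(seed)
    h = rng.uniform(0.1, 0.9, size=n_test)
    g = rng.binomial(1, h * p1 + (1 - h) * p0, size=n_test) \
        + rng.binomial(1, h * p1 + (1 - h) * p0, size=n_test)
    loci = pd.DataFrame({"chrom": ["1"], "pos": [100], "ref": ["A"],
                         "alt": ["G"], "id": ["v0"], "focal_is_alt": True})
    ids = [f"t{i}" for i in range(n_test)]
    gm = GenotypeMatrix(ids, loci, np.asarray(g, dtype=np.int8)[:, None])
    assign = PopulationAssignment({s: "TEST" for s in ids})
    freqs = diagnostic_freqs(loci, p0=p0, p1=p1)
    return gm, freqs, assign, h


def _grid_posterior_means(gm, freqs, h, prior_var=10.0):
    """Dense 2-D quadrature over (ln v, logit c) — the independent oracle.

    The grid must reach far into the prior's tails: with few observations
    the ln v posterior keeps substantial mass where the likelihood has
    plateaued and only the N(0, 10) prior decays.
    """
    g = gm.G[:, 0].astype(float)
    p0, p1 = freqs.p0[0], freqs.p1[0]
    lnv = np.linspace(-12, 6, 601)
    lgc = np.linspace(-16, 16, 601)
    LV, LC = np.meshgrid(lnv, lgc, indexing="ij")
    lp = -(LV**2 + LC**2) / (2 * prior_var)
    lh = logit(np.clip(h, 1e-9, 1 - 1e-9))
    for gi, lhi in zip(g, lh):
        phi = expit(np.exp(LV) * (lhi - LC))
        f = np.clip(phi * (p1 - p0) + p0, 1e-12, 1 - 1e-12)
        lp += gi * np.log(f) + (2 - gi) * np.log1p(-f)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return (w * LV).sum(), (w * LC).sum()


def test_mcmc_matches_grid_quadrature_oracle():
    gm, freqs, assign, h = _one_locus_data(seed=3)
    fit = cm.fit_cline(gm, freqs, h, assign, locus=0, nitt=260_000,
                       burnin=10_000, seed=5)
    lnv_g, lgc_g = _grid_posterior_means(gm, freqs, h)
    row = fit.table.iloc[0]
    assert row["lnv_mean"] == pytest.approx(lnv_g, abs=0.05)
    assert row["logitc_mean"] == pytest.approx(lgc_g, abs=0.05)


def test_fix_v_pins_steepness(prepared_sim):
    gm, freqs, assign, _ = prepared_sim
    hyb = cm.esth(gm, freqs, assign, nitt=600, burnin=300, seed=1)
    red = cm.fit_clines(gm, freqs, hyb, assign, nitt=500, burnin=250,
                        fix_v=True, seed=2)
    t = red.table
    assert (t.loc[t.flag == "ok", "lnv_mean"] == 0).all()
    assert (t.loc[t.flag == "ok", "lnv_var"] == 0).all()
    assert (t.loc[t.flag == "ok", "v_mean"] == 1).all()


def test_table_waic_consistent_with_compute_waic():
    """The vectorised fit's WAIC equals compute_waic applied to the
    reconstructed pointwise log-likelihood matrix of the stored draws."""
    gm, freqs, assign, h = _one_locus_data(seed=9, n_test=12)
    fit = cm.fit_cline(gm, freqs, h, assign, locus=0, nitt=800, burnin=400,
                       seed=7, keep_draws=True)
    p0, p1 = freqs.p0[0], freqs.p1[0]
    phi = expit(np.exp(fit.draws_lnv[:, 0])[None, :]
                * (logit(np.clip(h, 1e-9, 1 - 1e-9))[:, None]
                   - fit.draws_logitc[:, 0][None, :]))
    f = np.clip(phi * (p1 - p0) + p0, 1e-12, 1 - 1e-12)
    g = gm.G[:, 0].astype(float)
    rows = []
    for i in range(len(g)):
        rows += [np.log(f[i])] * int(g[i]) + [np.log1p(-f[i])] * int(2 - g[i])
    res = compute_waic(np.array(rows))
    row = fit.table.iloc[0]
    assert row["waic"] == pytest.approx(res.waic, abs=1e-8)
    assert row["p_waic"] == pytest.approx(res.p_waic, abs=1e-8)


def test_degenerate_locus_flagged(prepared_sim):
    gm, freqs, assign, _ = prepared_sim
    G = gm.G.copy()
    G[:, 0] = 2  # monomorphic among all usable observations
    gm2 = GenotypeMatrix(gm.sample_ids, gm.loci.copy(), G)
    hyb = cm.esth(gm2, freqs, assign, nitt=400, burnin=200, seed=1)
    fit = cm.fit_clines(gm2, freqs, hyb, assign, nitt=300, burnin=150, seed=2)
    assert fit.table["flag"].iloc[0] == "degenerate"
    assert np.isnan(fit.table["lnv_mean"].iloc[0])


def test_source_terms_constant_in_parameters(prepared_sim):
    """With p0, p1 fixed, source individuals only shift both models' WAIC by
    the same constant: delta-waic is unchanged by include_source."""
    gm, freqs, assign, _ = prepared_sim
    hyb = cm.esth(gm, freqs, assign, nitt=600, burnin=300, seed=3)
    kw = dict(nitt=500, burnin=250)
    m_with = cm.compare_models(
        cm.fit_clines(gm, freqs, hyb, assign, seed=5, **kw),
        cm.fit_clines(gm, freqs, hyb, assign, fix_v=True, seed=6, **kw))
    m_without = cm.compare_models(
        cm.fit_clines(gm, freqs, hyb, assign, seed=5, include_source=False,
                      **kw),
        cm.fit_clines(gm, freqs, hyb, assign, fix_v=True, seed=6,
                      include_source=False, **kw))
    assert np.allclose(m_with["delta_waic"], m_without["delta_waic"],
                       atol=1e-8)
    assert not np.allclose(m_with["waic_full"], m_without["waic_full"])


def test_determinism(prepared_sim):
    gm, freqs, assign, _ = prepared_sim
    hyb = cm.esth(gm, freqs, assign, nitt=400, burnin=200, seed=3)
    a = cm.fit_clines(gm, freqs, hyb, assign, nitt=400, burnin=200, seed=9)
    b = cm.fit_clines(gm, freqs, hyb, assign, nitt=400, burnin=200, seed=9)
    pd.testing.assert_frame_equal(a.table, b.table)
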