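"""Logit-logistic genomic cline fitting with WAIC model comparison.

The cline function maps an individual's genome-wide hybrid index h to the
probability that an allele copy at a locus is of S1 ancestry:

    phi(h; v, c) = logistic( v * (logit(h) - logit(c)) ),

with steepness v > 0 (v = 1: the locus tracks the genome-wide admixture;
v > 1: restricted gene flow) and centre c in (0, 1) (the hybrid index at
which the locus-specific allele frequency is halfway between the two source
frequencies; c != 0.5 indicates directionally biased introgression).

Parameters are sampled on the latent scale (ln v, logit c) — where the
posterior is close to bivariate normal — by a joint adaptive random-walk
Metropolis, with independent Normal(0, 10) priors on both latent parameters.
Each non-missing allele copy of individual i at locus l is the focal allele
with probability

    f_il = phi(h_i; v_l, c_l) * p1_l + (1 - phi(h_i; v_l, c_l)) * p0_l,

with h_i fixed at its posterior mean (source individuals enter at h = 0 or
h = 1 exactly, where their likelihood terms are constant in v and c) and
p0, p1 at their posterior means. Model support is assessed per locus by the
widely applicable information criterion, waic = -2 (lppd - p_waic), computed
from the per-allele-copy pointwise log-likelihood over posterior draws; a
reduced model re-fits each locus with v pinned to 1 and

    delta_waic = waic_full - waic_reduced,

negative values supporting steepness different from 1. All loci are fitted
simultaneously (chains vectorised across loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, logsumexp

from .genotypes import MISSING, GenotypeMatrix, PopulationAssignment
from .hybrid import HybridIndexEstimate
from .mcmc import adapt_log_scale, effective_sample_size
from .prep import SourceFreqs

__all__ = ["cline_function", "fit_clines", "fit_cline", "compute_waic",
           "compare_models", "WaicResult", "ClineFitTable"]

_H_EPS = 1e-9


def cline_function(h, v, c):
    """Probability phi(h; v, c) that an allele copy is of S1 ancestry.

    Strictly increasing in h for v > 0, with exact limits phi(0) = 0 and
    phi(1) = 1; phi(c) = 0.5 for any v. Accepts scalars or arrays.
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(v <= 0):
        raise ValueError("steepness v must be positive")
    if np.any((c <= 0) | (c >= 1)):
        raise ValueError("centre c must lie in (0, 1)")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hybrid index h must lie in [0, 1]")
    hc = np.clip(h, _H_EPS, 1 - _H_EPS)
    phi = expit(v * (logit(hc) - logit(c)))
    phi = np.where(h <= 0, 0.0, np.where(h >= 1, 1.0, phi))
    return phi if phi.ndim else float(phi)


# ---------------------------------------------------------------------------
# WAIC

@dataclass
class WaicResult:
    """waic = -2 (lppd - p_waic) from pointwise log-likelihood draws."""

    lppd: float
    p_waic: float
    waic: float
    n_obs: int
    n_draws: int


def compute_waic(ll: np.ndarray, weights: np.ndarray | None = None) -> WaicResult:
    """WAIC from an (n_obs, n_draws) matrix of pointwise log-likelihoods.

    lppd_j = log mean_s exp(ll_js) (log-sum-exp stabilised); p_waic_j is the
    sample variance over draws (ddof=1). Optional integer ``weights`` count
    duplicate observations sharing a row.
    """
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 2:
        raise ValueError("need an (n_obs, n_draws) matrix with n_draws >= 2")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite pointwise log-likelihoods")
    S = ll.shape[1]
    lppd_j = logsumexp(ll, axis=1) - np.log(S)
    p_waic_j = ll.var(axis=1, ddof=1)
    if weights is None:
        w = np.ones(ll.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    lppd = float(w @ lppd_j)
    p_waic = float(w @ p_waic_j)
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
                      n_obs=int(w.sum()), n_draws=S)


def compare_models(full: "ClineFitTable", reduced: "ClineFitTable") -> pd.DataFrame:
    """Merge a full and a v=1 reduced fit and compute delta_waic per locus.

    delta_waic = waic_full - waic_reduced; negative values support the full
    model. Both fits must cover the same loci with the same observation
    counts.
    """
    key = ["chrom", "pos", "ref", "alt"]
    a = full.table
    b = reduced.table[key + ["waic", "n_obs"]].rename(
        columns={"waic": "waic_reduced", "n_obs": "n_obs_reduced"})
    merged = a.merge(b, on=key, validate="one_to_one")
    if len(merged) != len(a):
        raise ValueError("full and reduced fits cover different loci")
    if not (merged["n_obs"] == merged["n_obs_reduced"]).all():
        raise ValueError("observation counts differ between full and reduced fits")
    merged = merged.rename(columns={"waic": "waic_full"})
    merged["delta_waic"] = merged["waic_full"] - merged["waic_reduced"]
    return merged.drop(columns=["n_obs_reduced"])


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class ClineFitTable:
    """Per-locus posterior summaries of one cline model fit.

    Columns: chrom, pos, ref, alt, lnv_mean, lnv_var, logitc_mean,
    logitc_var, latent_cov, v_mean, v_lo95, v_hi95, c_mean, c_lo95, c_hi95,
    u_mean, p_lnv, p_logitc, waic, lppd, p_waic, n_obs, ess_lnv, ess_logitc,
    accept_rate, flag.
    """

    table: pd.DataFrame
    nitt: int
    burnin: int
    seed: int
    fix_v: bool
    draws_lnv: np.ndarray | None = None
    draws_logitc: np.ndarray | None = None

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _prepare_observations(gm: GenotypeMatrix, assign: PopulationAssignment,
                          hybrid: HybridIndexEstimate | np.ndarray,
                          include_source: bool):
    """Genotype matrix restricted to usable individuals, with their h values."""
    labels = assign.as_series()
    ids, h = [], []
    if isinstance(hybrid, HybridIndexEstimate):
        hmap = hybrid.table.set_index("sample")["h_mean"].to_dict()
    else:
        hmap = dict(zip(gm.sample_ids, np.asarray(hybrid, dtype=float)))
    for s in gm.sample_ids:
        lab = labels.get(s)
        if lab == "TEST":
            if s not in hmap:
                raise ValueError(f"no hybrid index for test sample {s}")
            ids.append(s)
            h.append(float(hmap[s]))
        elif lab in ("S0", "S1") and include_source:
            ids.append(s)
            h.append(0.0 if lab == "S0" else 1.0)
    sub = gm.subset_samples(ids)
    return sub.G, np.asarray(h)


def fit_clines(gm: GenotypeMatrix, freqs: SourceFreqs,
               hybrid: HybridIndexEstimate | np.ndarray,
               assign: PopulationAssignment,
               prior_var_lnv: float = 10.0, prior_var_logitc: float = 10.0,
               nitt: int = 5000, burnin: int = 2000, fix_v: bool = False,
               include_source: bool = True, seed: int = 0,
               freq_update: str = "fixed", freq_seed: int | None = None,
               keep_draws: bool = False) -> ClineFitTable:
    """Fit the cline model at every locus of ``gm`` (vectorised chains).

    ``gm`` must be oriented and match ``freqs`` row for row (normally the
    retained subset from :func:`clinemap.prep.filter_ci_overlap`). With
    ``fix_v`` the steepness is pinned to v = 1 (ln v = 0, zero variance) and
    only logit(c) is sampled. Degenerate loci (no usable observations, or
    all observations identical with both sources empty) are flagged rather
    than forced.

    ``freq_update`` selects how source allele frequencies are treated:
    ``"fixed"`` (default) pins p0, p1 at their posterior means — fast and
    deterministic; ``"resample"`` redraws them from their source-only Beta
    posteriors every iteration, a conservative sensitivity analysis that
    propagates source-frequency uncertainty into the posterior and the
    WAIC. ``freq_seed`` controls the frequency draws separately from the
    main chain, so a full and a reduced fit given the same ``freq_seed``
    see identical frequency sequences (their source-observation WAIC terms
    then cancel exactly in delta-waic).
    """
    if nitt <= burnin:
        raise ValueError("nitt must exceed burnin")
    if len(freqs.table) != gm.n_loci:
        raise ValueError("SourceFreqs rows must match genotype loci")

    G, h = _prepare_observations(gm, assign, hybrid, include_source)
    n_ind, n_loci = G.shape
    p0 = np.clip(freqs.p0, 1e-9, 1 - 1e-9)
    p1 = np.clip(freqs.p1, 1e-9, 1 - 1e-9)

    # Source individuals (h exactly 0 or 1) contribute likelihood terms
    # constant in (v, c): split them out of the sampled part.
    is_test = (h > 0.0) & (h < 1.0)
    Gt = G[is_test].astype(np.float64)
    mask_t = G[is_test] != MISSING
    Gt_eff = np.where(mask_t, Gt, 0.0)
    two_eff = np.where(mask_t, 2.0 - Gt, 0.0)
    logit_h = logit(np.clip(h[is_test], _H_EPS, 1 - _H_EPS))

    # per-locus focal/total allele-copy counts among included source
    # individuals (their likelihood terms do not involve v or c)
    Gs = G[~is_test]
    hs = h[~is_test]
    mask_s = Gs != MISSING
    s1_rows = hs >= 1.0
    ks0 = np.where(mask_s[~s1_rows], Gs[~s1_rows], 0).sum(axis=0).astype(float)
    m0 = 2.0 * mask_s[~s1_rows].sum(axis=0)
    ks1 = np.where(mask_s[s1_rows], Gs[s1_rows], 0).sum(axis=0).astype(float)
    m1 = 2.0 * mask_s[s1_rows].sum(axis=0)
    n_obs_source = (m0 + m1).astype(int)

    usable = (mask_t.sum(axis=0) + mask_s.sum(axis=0)) > 0
    # loci monomorphic among usable observations cannot move the likelihood
    allele_counts = Gt_eff.sum(axis=0) + np.where(mask_s, Gs, 0).sum(axis=0)
    total_copies = 2.0 * (mask_t.sum(axis=0) + mask_s.sum(axis=0))
    mono = usable & ((allele_counts == 0) | (allele_counts == total_copies))

    if freq_update not in ("fixed", "resample"):
        raise ValueError("freq_update must be 'fixed' or 'resample'")
    resample_freqs = freq_update != "fixed"
    rng = np.random.default_rng(seed)
    lnv = np.zeros(n_loci)
    logitc = np.zeros(n_loci)
    if resample_freqs:
        a0, b0, a1, b1 = freqs.beta_params()
        rng_f = np.random.default_rng(seed + 7919 if freq_seed is None
                                      else freq_seed)

    def loglik(lnv_a, logitc_a, p0a, p1a) -> np.ndarray:
        v = np.exp(lnv_a)
        phi = expit(v[None, :] * (logit_h[:, None] - logitc_a[None, :]))
        f = phi * (p1a - p0a)[None, :] + p0a[None, :]
        np.clip(f, 1e-12, 1 - 1e-12, out=f)
        return (Gt_eff * np.log(f) + two_eff * np.log1p(-f)).sum(axis=0)

    def logprior(lnv_a: np.ndarray, logitc_a: np.ndarray) -> np.ndarray:
        lp = -0.5 * logitc_a**2 / prior_var_logitc
        if not fix_v:
            lp = lp - 0.5 * lnv_a**2 / prior_var_lnv
        return lp

    lp = loglik(lnv, logitc, p0, p1) + logprior(lnv, logitc)
    log_step = np.full(n_loci, np.log(0.3))
    n_keep = nitt - burnin
    d_lnv = np.empty((n_keep, n_loci))
    d_logitc = np.empty((n_keep, n_loci))
    if resample_freqs:
        d_p0 = np.empty((n_keep, n_loci))
        d_p1 = np.empty((n_keep, n_loci))
    n_acc = np.zeros(n_loci)
    target = 0.35 if fix_v else 0.25  # joint 2-D walk mixes best below 0.44

    p0_it, p1_it = p0, p1

    for it in range(1, nitt + 1):
        if resample_freqs:
            p0_it = np.clip(rng_f.beta(a0, b0), 1e-9, 1 - 1e-9)
            p1_it = np.clip(rng_f.beta(a1, b1), 1e-9, 1 - 1e-9)
            lp = loglik(lnv, logitc, p0_it, p1_it) + logprior(lnv, logitc)
        step = np.exp(log_step)
        prop_c = logitc + step * rng.normal(size=n_loci)
        if fix_v:
            prop_v = lnv
        else:
            prop_v = lnv + step * rng.normal(size=n_loci)
        lpp = loglik(prop_v, prop_c, p0_it, p1_it) + logprior(prop_v, prop_c)
        accept = np.log(rng.uniform(size=n_loci)) < (lpp - lp)
        lnv = np.where(accept, prop_v, lnv)
        logitc = np.where(accept, prop_c, logitc)
        lp = np.where(accept, lpp, lp)
        if it <= burnin:
            adapt_log_scale(log_step, accept, it, target=target)
        else:
            d_lnv[it - burnin - 1] = lnv
            d_logitc[it - burnin - 1] = logitc
            if resample_freqs:
                d_p0[it - burnin - 1] = p0_it
                d_p1[it - burnin - 1] = p1_it
            n_acc += accept

    # summaries -------------------------------------------------------------
    lnv_mean = d_lnv.mean(axis=0)
    logitc_mean = d_logitc.mean(axis=0)
    lnv_var = d_lnv.var(axis=0, ddof=1)
    logitc_var = d_logitc.var(axis=0, ddof=1)
    latent_cov = ((d_lnv - lnv_mean) * (d_logitc - logitc_mean)).sum(axis=0) \
        / (n_keep - 1)
    v_draws = np.exp(d_lnv)
    c_draws = expit(d_logitc)
    v_mean = v_draws.mean(axis=0)
    c_mean = c_draws.mean(axis=0)
    v_lo, v_hi = np.quantile(v_draws, [0.025, 0.975], axis=0)
    c_lo, c_hi = np.quantile(c_draws, [0.025, 0.975], axis=0)
    u_mean = (v_draws * d_logitc).mean(axis=0)

    def _pnorm_two_sided(mean, var):
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, np.abs(mean) / sd, np.inf)
        return 2.0 * stats.norm.sf(z)

    p_lnv = (np.full(n_loci, np.nan) if fix_v
             else _pnorm_two_sided(lnv_mean, lnv_var))
    p_logitc = _pnorm_two_sided(logitc_mean, logitc_var)
    ess_lnv = (np.full(n_loci, np.nan) if fix_v
               else effective_sample_size(d_lnv))
    ess_logitc = effective_sample_size(d_logitc)

    # pointwise WAIC over allele copies, from the stored draws -------------
    lppd = np.zeros(n_loci)
    p_waic = np.zeros(n_loci)
    S = float(n_keep)

    def _wvar(sq_mean, mean):
        return np.clip((sq_mean - mean**2) * (S / (S - 1.0)), 0.0, None)

    if not resample_freqs:
        # Rejected proposals repeat the previous state, so each locus chain
        # has far fewer unique (ln v, logit c) states than draws: evaluate
        # the pointwise likelihood once per unique state and weight by its
        # run-length multiplicity (exact, just cheaper).
        for j in range(n_loci):
            lv = d_lnv[:, j]
            lc = d_logitc[:, j]
            change = np.empty(n_keep, dtype=bool)
            change[0] = True
            np.not_equal(lv[1:], lv[:-1], out=change[1:])
            change[1:] |= lc[1:] != lc[:-1]
            starts = np.flatnonzero(change)
            w = np.diff(np.append(starts, n_keep)).astype(float)
            # f: (n_test, n_unique)
            f = expit(np.exp(lv[starts])[None, :]
                      * (logit_h[:, None] - lc[starts][None, :]))
            f *= (p1[j] - p0[j])
            f += p0[j]
            np.clip(f, 1e-12, 1 - 1e-12, out=f)
            A = np.log(f)
            fm = f @ w / S                  # mean over draws of exp(ll), y=1
            mA = A @ w / S
            vA = _wvar((A * A) @ w / S, mA)
            fm1 = 1.0 - fm                  # mean over draws of exp(ll), y=0
            np.negative(f, out=f)
            B = np.log1p(f, out=f)          # log(1 - f), reusing the buffer
            mB = B @ w / S
            vB = _wvar((B * B) @ w / S, mB)
            g = Gt_eff[:, j]
            t = two_eff[:, j]
            lppd[j] = g @ np.log(fm) + t @ np.log(fm1)
            p_waic[j] = g @ vA + t @ vB
        # source observations: f constant over draws -> zero variance
        lppd += (ks0 * np.log(p0) + (m0 - ks0) * np.log1p(-p0)
                 + ks1 * np.log(p1) + (m1 - ks1) * np.log1p(-p1))
    else:
        # frequencies vary per draw: full per-draw pointwise likelihoods
        for j in range(n_loci):
            f = expit(np.exp(d_lnv[:, j])[None, :]
                      * (logit_h[:, None] - d_logitc[:, j][None, :]))
            f *= (d_p1[:, j] - d_p0[:, j])[None, :]
            f += d_p0[:, j][None, :]
            np.clip(f, 1e-12, 1 - 1e-12, out=f)
            A = np.log(f)
            fm = f.mean(axis=1)
            vA = _wvar((A * A).mean(axis=1), A.mean(axis=1))
            fm1 = 1.0 - fm
            np.negative(f, out=f)
            B = np.log1p(f, out=f)
            vB = _wvar((B * B).mean(axis=1), B.mean(axis=1))
            g = Gt_eff[:, j]
            t = two_eff[:, j]
            lppd[j] = g @ np.log(fm) + t @ np.log(fm1)
            p_waic[j] = g @ vA + t @ vB
        # source observations share the per-draw frequency sequences
        for pd_, k_, mtot in ((d_p0, ks0, m0), (d_p1, ks1, m1)):
            Lp = np.log(pd_)
            lppd += k_ * np.log(pd_.mean(axis=0))
            p_waic += k_ * _wvar((Lp * Lp).mean(axis=0), Lp.mean(axis=0))
            Lq = np.log1p(-pd_)
            lppd += (mtot - k_) * np.log1p(-pd_.mean(axis=0))
            p_waic += (mtot - k_) * _wvar((Lq * Lq).mean(axis=0),
                                          Lq.mean(axis=0))
    waic = -2.0 * (lppd - p_waic)
    n_obs = 2 * mask_t.sum(axis=0) + n_obs_source

    flag = np.where(~usable, "no_data", np.where(mono, "degenerate", "ok"))
    bad = flag != "ok"
    if fix_v:
        lnv_mean = np.zeros(n_loci)
        lnv_var = np.zeros(n_loci)
        latent_cov = np.zeros(n_loci)
        v_mean = np.ones(n_loci)
        v_lo = np.ones(n_loci)
        v_hi = np.ones(n_loci)

    table = gm.loci[["chrom", "pos", "ref", "alt"]].copy()
    table["lnv_mean"] = np.where(bad, np.nan, lnv_mean)
    table["lnv_var"] = np.where(bad, np.nan, lnv_var)
    table["logitc_mean"] = np.where(bad, np.nan, logitc_mean)
    table["logitc_var"] = np.where(bad, np.nan, logitc_var)
    table["latent_cov"] = np.where(bad, np.nan, latent_cov)
    table["v_mean"] = np.where(bad, np.nan, v_mean)
    table["v_lo95"] = np.where(bad, np.nan, v_lo)
    table["v_hi95"] = np.where(bad, np.nan, v_hi)
    table["c_mean"] = np.where(bad, np.nan, c_mean)
    table["c_lo95"] = np.where(bad, np.nan, c_lo)
    table["c_hi95"] = np.where(bad, np.nan, c_hi)
    table["u_mean"] = np.where(bad, np.nan, u_mean)
    table["p_lnv"] = np.where(bad, np.nan, p_lnv)
    table["p_logitc"] = np.where(bad, np.nan, p_logitc)
    table["waic"] = np.where(bad, np.nan, waic)
    table["lppd"] = np.where(bad, np.nan, lppd)
    table["p_waic"] = np.where(bad, np.nan, p_waic)
    table["n_obs"] = n_obs
    table["ess_lnv"] = ess_lnv
    table["ess_logitc"] = ess_logitc
    table["accept_rate"] = n_acc / n_keep
    table["flag"] = flag
    return ClineFitTable(table, nitt=nitt, burnin=burnin, seed=seed,
                         fix_v=fix_v,
                         draws_lnv=d_lnv if keep_draws else None,
                         draws_logitc=d_logitc if keep_draws else None)


def fit_cline(gm: GenotypeMatrix, freqs: SourceFreqs,
              hybrid: HybridIndexEstimate | np.ndarray,
              assign: PopulationAssignment, locus: int = 0,
              **kwargs) -> ClineFitTable:
    """Single-locus convenience wrapper around :func:`fit_clines`."""
    sub = gm.subset_loci(np.array([locus]))
    f = SourceFreqs(freqs.table.iloc[[locus]].reset_index(drop=True))
    return fit_clines(sub, f, hybrid, assign, **kwargs)
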