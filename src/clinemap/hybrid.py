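"""Bayesian hybrid-index estimation by adaptive random-walk MCMC.

The hybrid index h of an individual is the proportion of its genome derived
from source population S1. Given per-locus source allele frequencies p0, p1
(fixed at their posterior means), each non-missing allele copy at locus l is
the focal allele with probability

    f_il = h_i * p1_l + (1 - h_i) * p0_l,

so each sample's posterior factorises over loci and samples are estimated by
independent chains. Sampling is a random-walk Metropolis on logit(h) with a
Beta prior on h, step sizes adapted toward ~0.44 acceptance during burn-in
only. All chains are advanced simultaneously (vectorised across samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotypes import MISSING, GenotypeMatrix, PopulationAssignment
from .mcmc import adapt_log_scale, diagnose_chain, effective_sample_size
from .prep import SourceFreqs

__all__ = ["HybridIndexEstimate", "esth", "diagnose_chain"]

_H_EPS = 1e-6  # keep logit(h) finite; boundary behaviour comes from the prior


@dataclass
class HybridIndexEstimate:
    """Posterior summaries of per-sample hybrid indices.

    ``table`` columns: sample, label, h_mean, h_sd, h_lo95, h_hi95, ess,
    accept_rate. ``draws`` (optional) holds the post-burn-in chains,
    shape (n_draws, n_samples), sample order as in ``table``.
    """

    table: pd.DataFrame
    nitt: int
    burnin: int
    seed: int
    draws: np.ndarray | None = None

    def h_for(self, sample_ids: list[str]) -> np.ndarray:
        s = self.table.set_index("sample")["h_mean"]
        return s.loc[sample_ids].to_numpy()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _loglik_h(h: np.ndarray, G: np.ndarray, mask: np.ndarray,
              p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Log-likelihood of each sample's h; G is (n_samples, n_loci)."""
    f = h[:, None] * (p1 - p0)[None, :] + p0[None, :]
    np.clip(f, 1e-12, 1 - 1e-12, out=f)
    ll = G * np.log(f) + (2.0 - G) * np.log1p(-f)
    return np.where(mask, ll, 0.0).sum(axis=1)


def esth(gm: GenotypeMatrix, freqs: SourceFreqs, assign: PopulationAssignment,
         prior: tuple[float, float] = (1.0, 1.0), nitt: int = 2000,
         burnin: int = 1000, seed: int = 0, samples: str = "all",
         resample_freqs: bool = False, freq_seed: int | None = None,
         keep_draws: bool = False) -> HybridIndexEstimate:
    """Estimate hybrid indices for test (and optionally source) samples.

    ``gm`` must already be oriented and restricted to retained loci (its
    locus table must match ``freqs`` row for row). ``samples`` is "all" or
    "test". With ``resample_freqs`` the source frequencies are redrawn from
    their Beta posteriors each iteration instead of being fixed at posterior
    means (sensitivity analysis / uncertainty propagation). Identical
    (seed, sample set) gives identical results.
    """
    if nitt <= burnin:
        raise ValueError("nitt must exceed burnin")
    if len(freqs.table) != gm.n_loci:
        raise ValueError("SourceFreqs rows must match genotype loci")

    labels = assign.as_series()
    if samples == "test":
        ids = [s for s in gm.sample_ids if labels.get(s) == "TEST"]
    elif samples == "all":
        ids = [s for s in gm.sample_ids
               if labels.get(s) in ("S0", "S1", "TEST")]
    else:
        raise ValueError("samples must be 'all' or 'test'")
    sub = gm.subset_samples(ids)
    Gm = sub.G.astype(np.float64)
    mask = sub.G != MISSING
    if not mask.any(axis=1).all():
        bad = [ids[i] for i in np.nonzero(~mask.any(axis=1))[0]]
        raise ValueError(f"samples with zero usable genotypes: {bad[:5]}")
    p0, p1 = freqs.p0, freqs.p1

    rng = np.random.default_rng(seed)
    n = len(ids)
    a_pr, b_pr = prior

    # prior density of h mapped to the logit scale (includes the Jacobian)
    def logprior(theta, h):
        return a_pr * np.log(h) + b_pr * np.log1p(-h)

    if resample_freqs:
        a0, b0, a1, b1 = freqs.beta_params()
        rng_f = np.random.default_rng(seed + 7919 if freq_seed is None
                                      else freq_seed)

    theta = rng.normal(0.0, 0.5, size=n)  # logit(h)
    h = np.clip(expit(theta), _H_EPS, 1 - _H_EPS)
    lp = _loglik_h(h, Gm, mask, p0, p1) + logprior(theta, h)
    log_step = np.full(n, np.log(0.5))
    n_keep = nitt - burnin
    draws = np.empty((n_keep, n), dtype=float)
    n_acc = np.zeros(n)

    for it in range(1, nitt + 1):
        if resample_freqs:
            p0 = np.clip(rng_f.beta(a0, b0), 1e-9, 1 - 1e-9)
            p1 = np.clip(rng_f.beta(a1, b1), 1e-9, 1 - 1e-9)
            lp = _loglik_h(h, Gm, mask, p0, p1) + logprior(theta, h)
        prop = theta + np.exp(log_step) * rng.normal(size=n)
        hp = np.clip(expit(prop), _H_EPS, 1 - _H_EPS)
        lpp = _loglik_h(hp, Gm, mask, p0, p1) + logprior(prop, hp)
        accept = np.log(rng.uniform(size=n)) < (lpp - lp)
        theta = np.where(accept, prop, theta)
        h = np.where(accept, hp, h)
        lp = np.where(accept, lpp, lp)
        if it <= burnin:
            adapt_log_scale(log_step, accept, it, target=0.44)
        else:
            draws[it - burnin - 1] = h
            n_acc += accept

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    ess = effective_sample_size(draws)
    table = pd.DataFrame({
        "sample": ids,
        "label": [labels.get(s) for s in ids],
        "h_mean": mean, "h_sd": sd, "h_lo95": lo, "h_hi95": hi,
        "ess": ess, "accept_rate": n_acc / n_keep,
    })
    return HybridIndexEstimate(table, nitt=nitt, burnin=burnin, seed=seed,
                               draws=draws if keep_draws else None)
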