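"""Shared MCMC machinery: adaptive random-walk scales and chain diagnostics.

The samplers in :mod:`clinemap.hybrid` and :mod:`clinemap.cline` are plain
adaptive random-walk Metropolis chains on unconstrained (logit / log) scales.
Step sizes adapt by Robbins–Monro updates toward a target acceptance rate
during burn-in only, so post-burn-in transition kernels are fixed and satisfy
detailed balance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["effective_sample_size", "geweke_z", "diagnose_chain", "adapt_log_scale"]


def adapt_log_scale(log_scale: np.ndarray, accepted: np.ndarray, iteration: int,
                    target: float, rate: float = 1.0) -> None:
    """Robbins–Monro update of per-chain log step sizes, in place.

    ``accepted`` is a boolean (or 0/1) array of per-chain acceptance
    indicators for this iteration; ``iteration`` is 1-based.
    """
    gamma = rate / np.sqrt(iteration)
    log_scale += gamma * (np.asarray(accepted, dtype=float) - target)


def _autocovariance_fft(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of each column of ``x`` (draws along axis 0)."""
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (n, m)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:n].real
    return acov / n


def effective_sample_size(draws: np.ndarray) -> np.ndarray | float:
    """Autocorrelation-based ESS (Geyer initial monotone positive sequence).

    ``draws`` has draws along axis 0; an optional second axis gives multiple
    chains evaluated independently (vectorised via FFT autocovariance).
    """
    x = np.asarray(draws, dtype=float)
    scalar = x.ndim == 1
    if scalar:
        x = x[:, None]
    n, m = x.shape
    if n < 4:
        out = np.full(m, float(n))
        return float(out[0]) if scalar else out
    acov = _autocovariance_fft(x)
    var0 = acov[0]
    ess = np.full(m, float(n))
    ok = var0 > 0
    # Geyer: sum consecutive pairs of autocorrelations while positive and
    # non-increasing.
    for j in np.nonzero(ok)[0]:
        rho = acov[:, j] / var0[j]
        tau = 1.0
        prev = np.inf
        t = 1
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            pair = min(pair, prev)
            tau += 2.0 * pair
            prev = pair
            t += 2
        ess[j] = n / max(tau, 1.0 / n)
    ess = np.minimum(ess, n)
    return float(ess[0]) if scalar else ess


def geweke_z(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means.

    Segment standard errors use the segment variance deflated by the
    segment's own effective sample size.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    a = x[: max(int(first * n), 2)]
    b = x[n - max(int(last * n), 2):]

    def _se(seg: np.ndarray) -> float:
        v = seg.var(ddof=1)
        if v == 0:
            return 0.0
        return float(np.sqrt(v / effective_sample_size(seg)))

    se = np.hypot(_se(a), _se(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


def diagnose_chain(draws: np.ndarray, ess_warn: float = 100.0,
                   z_warn: float = 3.0) -> dict:
    """Summarise a single post-burn-in chain.

    Returns ESS, Geweke z and a ``warn`` flag raised when ESS < ``ess_warn``
    or |z| > ``z_warn``. Requires at least 100 draws.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 post-burn-in draws to diagnose")
    ess = float(effective_sample_size(x))
    z = geweke_z(x)
    return {"ess": ess, "geweke_z": z, "warn": bool(ess < ess_warn or abs(z) > z_warn)}
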