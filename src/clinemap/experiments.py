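"""Canned simulation experiments: null calibration and recovery studies.

These functions define the package's standard synthetic protocols end to
end — simulate, estimate source frequencies (EB-shrunk), filter, estimate
hybrid indices, fit full and reduced clines, compare — so the calibration
numbers quoted in the documentation are reproducible from a single call.
They are used by the analysis drivers, the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cline, hybrid, prep, simulate
from .prep import SourceFreqs

__all__ = ["null_calibration", "recovery_study", "NullCalibration",
           "RecoveryStudy"]


@dataclass
class NullCalibration:
    """Result of the null-model calibration experiment."""

    merged: pd.DataFrame          # compare_models output
    fpr_dwaic2: float             # % of loci with delta_waic < -2
    fpr_scv: float                # % of loci passing the full SCV criterion
    h_rmse: float
    n_loci: int


def _prepare(config: simulate.SimConfig, esth_nitt: int, esth_burnin: int,
             seed: int):
    gm, assign, truth = simulate.simulate_dataset(config)
    gm, freqs = prep.estimate_source_freqs(gm, assign)
    freqs, gm = prep.filter_ci_overlap(freqs, gm)
    freqs = prep.eb_shrink_freqs(freqs)
    hyb = hybrid.esth(gm, freqs, assign, nitt=esth_nitt, burnin=esth_burnin,
                      seed=seed + 1)
    tru = truth.individuals.set_index("sample")
    tm = hyb.table[hyb.table.label == "TEST"].set_index("sample")
    h_rmse = float(np.sqrt(((tm["h_mean"] - tru.loc[tm.index, "h"])**2).mean()))
    return gm, assign, truth, freqs, hyb, h_rmse


def _fit_pair(gm, freqs, hyb, assign, nitt, burnin, seed):
    full = cline.fit_clines(gm, freqs, hyb, assign, nitt=nitt, burnin=burnin,
                            seed=seed + 2)
    reduced = cline.fit_clines(gm, freqs, hyb, assign, nitt=nitt,
                               burnin=burnin, fix_v=True, seed=seed + 3)
    return cline.compare_models(full, reduced)


def null_calibration(seed: int, n_loci: int = 2000, n_test: int = 200,
                     n_source: int = 20,
                     cline_nitt: int = 5000, cline_burnin: int = 2000,
                     esth_nitt: int = 2000, esth_burnin: int = 1000
                     ) -> NullCalibration:
    """False-positive rates of delta-waic thresholds under the null cline.

    Every locus is simulated with v = 1, c = 0.5 (strongly divergent
    sources, p0 ~ U(0, 0.1), p1 ~ U(0.9, 1); test hybrid indices
    ~ U(0.1, 0.9)); the full pipeline is run and the percentage of loci
    with delta_waic < -2 — the mild support threshold — is reported, along
    with the rate for the conservative SCV criterion
    (ln v > 2.3 and delta_waic < -10).
    """
    config = simulate.SimConfig(
        n_s0=n_source, n_s1=n_source, n_test=n_test, n_loci=n_loci,
        missing_rate=0.0, h_range=(0.1, 0.9),
        freq_model=simulate.FreqModel(p0_range=(0.0, 0.1),
                                      p1_range=(0.9, 1.0)),
        seed=seed)
    gm, assign, _truth, freqs, hyb, h_rmse = _prepare(
        config, esth_nitt, esth_burnin, seed)
    merged = _fit_pair(gm, freqs, hyb, assign, cline_nitt, cline_burnin, seed)
    dw = merged["delta_waic"].to_numpy()
    lnv = merged["lnv_mean"].to_numpy()
    ok = np.isfinite(dw)
    return NullCalibration(
        merged=merged,
        fpr_dwaic2=100.0 * float(np.mean(dw[ok] < -2.0)),
        fpr_scv=100.0 * float(np.mean((dw[ok] < -10.0) & (lnv[ok] > 2.3))),
        h_rmse=h_rmse, n_loci=int(ok.sum()))


@dataclass
class RecoveryStudy:
    """Result of the barrier-locus recovery experiment."""

    merged: pd.DataFrame          # cline comparison on the fitted subset
    true_lnv: np.ndarray          # aligned to merged rows
    truth: simulate.SimTruth
    hybrid: "hybrid.HybridIndexEstimate"
    h_rmse: float

    def subset(self, lnv_value: float) -> pd.DataFrame:
        m = np.isclose(self.true_lnv, lnv_value)
        return self.merged.loc[m]

    def power_scv(self, lnv_value: float, lnv_threshold: float = 2.3,
                  dwaic_threshold: float = -10.0) -> float:
        sub = self.subset(lnv_value)
        hit = (sub["lnv_mean"] > lnv_threshold) \
            & (sub["delta_waic"] < dwaic_threshold)
        return float(hit.mean())


def recovery_study(seed: int, n_loci: int = 20_000, n_test: int = 200,
                   n_source: int = 20, n_null_fit: int = 600,
                   barrier_spec: list[simulate.BarrierSpec] | None = None,
                   cline_nitt: int = 5000, cline_burnin: int = 2000,
                   esth_nitt: int = 2000, esth_burnin: int = 1000
                   ) -> RecoveryStudy:
    """Steep-cline recovery with hybrid indices from a large neutral panel.

    Mirrors the structure of a real analysis: hybrid indices come from a
    large, overwhelmingly neutral marker panel (here ``n_loci`` loci of
    which barrier loci are a small fraction — in real admixed genomes the
    hybrid index is estimated from millions of pruned variants, so its
    error is negligible; a too-small panel attenuates steep-cline recovery
    through noise in logit(h) near the cline centre), while clines are
    fitted per locus on the loci of interest (all barrier loci plus
    ``n_null_fit`` neutral loci). The default barrier set is 100 loci at
    ln v = 2.7 (the SCV power point), 60 at ln v = 2.5 and a clustered run
    of 15 at ln v = 2.7 / 5 kb spacing for region-pooling checks.
    """
    if barrier_spec is None:
        barrier_spec = [
            simulate.BarrierSpec(100 / n_loci, 2.7, 0.5),
            simulate.BarrierSpec(60 / n_loci, 2.5, 0.5),
            simulate.BarrierSpec(15 / n_loci, 2.7, 0.5, clustered=True),
        ]
    config = simulate.SimConfig(
        n_s0=n_source, n_s1=n_source, n_test=n_test, n_loci=n_loci,
        missing_rate=0.0, h_range=(0.1, 0.9),
        freq_model=simulate.FreqModel(p0_range=(0.0, 0.1),
                                      p1_range=(0.9, 1.0)),
        barrier_spec=barrier_spec, seed=seed)
    gm, assign, truth, freqs, hyb, h_rmse = _prepare(
        config, esth_nitt, esth_burnin, seed)

    key = pd.MultiIndex.from_arrays([gm.loci["chrom"], gm.loci["pos"]])
    tl = truth.loci.set_index(["chrom", "pos"]).loc[key]
    tv = tl["lnv"].to_numpy()
    rng = np.random.default_rng(seed + 17)
    null_idx = np.flatnonzero(tv == 0)
    pick = rng.choice(null_idx, size=min(n_null_fit, null_idx.size),
                      replace=False)
    idx = np.sort(np.r_[np.flatnonzero(tv > 0), pick])
    sub = gm.subset_loci(idx)
    fsub = SourceFreqs(freqs.table.iloc[idx].reset_index(drop=True))
    merged = _fit_pair(sub, fsub, hyb, assign, cline_nitt, cline_burnin, seed)
    return RecoveryStudy(merged=merged, true_lnv=tv[idx], truth=truth,
                         hybrid=hyb, h_rmse=h_rmse)
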