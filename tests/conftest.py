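"""Shared fixtures: small simulated hybrid-zone datasets.

The heavyweight recovery/calibration studies used by the acceptance tests
are session-scoped so several tests can share one MCMC run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clinemap as cm
from clinemap.prep import SourceFreqs


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed panel: 100 loci, 12+12 source and 60 test samples."""
    cfg = cm.SimConfig(n_s0=12, n_s1=12, n_test=60, n_loci=100, seed=7,
                       missing_rate=0.02)
    gm, assign, truth = cm.simulate_dataset(cfg)
    return cfg, gm, assign, truth


@pytest.fixture(scope="session")
def prepared_sim(small_sim):
    """The small panel taken through frequency estimation and filtering."""
    _cfg, gm, assign, truth = small_sim
    gm2, freqs = cm.estimate_source_freqs(gm, assign)
    freqs_ret, gm_ret = cm.filter_ci_overlap(freqs, gm2)
    return gm_ret, freqs_ret, assign, truth


def diagnostic_freqs(loci: pd.DataFrame, p0: float = 0.0, p1: float = 1.0
                     ) -> SourceFreqs:
    """SourceFreqs fixture with exact (typically diagnostic) frequencies."""
    n = len(loci)
    tbl = loci[["chrom", "pos", "ref", "alt"]].copy()
    tbl["flipped"] = False
    tbl["k0"], tbl["n0"] = 0.0, 40.0
    tbl["k1"], tbl["n1"] = 40.0, 40.0
    tbl["p0_mean"], tbl["p0_lo"], tbl["p0_hi"] = p0, p0, p0
    tbl["p1_mean"], tbl["p1_lo"], tbl["p1_hi"] = p1, p1, p1
    tbl["a0"], tbl["b0"] = 0.5, 40.5
    tbl["a1"], tbl["b1"] = 40.5, 0.5
    tbl["usable"], tbl["retained"] = True, True
    return SourceFreqs(tbl)


@pytest.fixture(scope="session")
def recovery_run():
    """Large recovery study shared by the acceptance tests (one MCMC run).

    Hybrid indices come from a 12k-locus, almost entirely neutral panel;
    clines are fitted on all barrier loci (100 at ln v = 2.7, 60 at 2.5,
    one clustered run of 15 at 2.7) plus 600 neutral loci.
    """
    from clinemap.experiments import recovery_study
    return recovery_study(seed=202)


@pytest.fixture(scope="session")
def null_run():
    """Null-model calibration study shared by the acceptance tests."""
    from clinemap.experiments import null_calibration
    return null_calibration(seed=101, n_loci=1000)
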