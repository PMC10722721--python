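"""Downstream association statistics for cline-analysis outputs.

Covers: Weir & Cockerham multi-population FST, ANOVA of cline steepness
across FST bins, OLS of ln(v) on variant-consequence categories, the
SNP/indel Mann-Whitney comparison, recombination hotspot/coldspot
categorisation with category regressions (Tukey HSD contrasts), the
centre-class chi-square, and plain Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["weir_fst_multipop", "fst_group_anova", "effect_regression",
           "snp_indel_test", "classify_recomb", "recomb_category_regression",
           "centre_class_chisq", "correlate", "variant_type"]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) multi-population theta

def weir_fst_multipop(gm: GenotypeMatrix, pop_labels: dict[str, str] | pd.Series
                      ) -> pd.DataFrame:
    """Per-locus Weir & Cockerham theta across r subpopulations.

    Uses per-population focal-allele frequencies and observed heterozygote
    proportions; missing genotypes are excluded per locus per population, and
    populations with no data at a locus drop out of that locus's estimate.
    Loci usable in fewer than two populations get NaN. ``fst_clamped`` sets
    negative estimates to zero.
    """
    labels = pd.Series(pop_labels)
    pops = sorted(labels.unique())
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    L = gm.n_loci
    r_max = len(pops)
    n_mat = np.zeros((r_max, L))      # individuals with data
    p_mat = np.zeros((r_max, L))      # focal allele frequency
    h_mat = np.zeros((r_max, L))      # observed het proportion
    for k, pop in enumerate(pops):
        rows = [idx[s] for s in labels.index[labels == pop] if s in idx]
        if len(rows) < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")
        sub = gm.G[rows]
        nm = sub != MISSING
        n_k = nm.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_mat[k] = np.where(nm, sub, 0).sum(axis=0) / (2.0 * n_k)
            h_mat[k] = np.where(nm & (sub == 1), 1.0, 0.0).sum(axis=0) / n_k
        n_mat[k] = n_k

    has = n_mat > 0
    r = has.sum(axis=0).astype(float)
    ok = r >= 2
    n_mat = np.where(has, n_mat, 0.0)
    p_mat = np.where(has, p_mat, 0.0)
    h_mat = np.where(has, h_mat, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_mat.sum(axis=0) / r
        nc = (n_mat.sum(axis=0) - (n_mat**2).sum(axis=0) / n_mat.sum(axis=0)) \
            / (r - 1)
        pbar = (n_mat * p_mat).sum(axis=0) / (r * nbar)
        s2 = (n_mat * (p_mat - pbar[None, :])**2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_mat * h_mat).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        cc = hbar / 2.0
        denom = a + b + cc
        theta = np.where(ok & (denom != 0), a / denom, np.nan)

    out = gm.loci[["chrom", "pos", "ref", "alt"]].copy()
    out["fst_raw"] = theta
    out["fst_clamped"] = np.where(np.isnan(theta), np.nan,
                                  np.clip(theta, 0.0, None))
    out["n_pops"] = r.astype(int)
    return out


# ---------------------------------------------------------------------------
# FST-group ANOVA

def fst_group_anova(fst: pd.Series | np.ndarray, lnv: pd.Series | np.ndarray,
                    bin_edges: list[float] | None = None) -> dict:
    """One-way ANOVA of ln(v) across FST bins, plus Pearson correlation.

    Default bins are 0.05 wide up to 0.4 with a terminal (0.4, 1] bin. Empty
    bins are dropped with a warning.
    """
    if bin_edges is None:
        bin_edges = [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 1.0]
    fst = np.asarray(fst, dtype=float)
    lnv = np.asarray(lnv, dtype=float)
    ok = np.isfinite(fst) & np.isfinite(lnv)
    fst, lnv = fst[ok], lnv[ok]
    cats = pd.cut(fst, bin_edges, include_lowest=True)
    groups, means, ns, labels = [], [], [], []
    for level in cats.categories:
        sel = np.asarray(cats == level)
        if sel.sum() == 0:
            log.warning("fst_group_anova: empty bin %s dropped", level)
            continue
        groups.append(lnv[sel])
        means.append(float(np.mean(groups[-1])))
        ns.append(int(sel.sum()))
        labels.append(str(level))
    if len(groups) < 2:
        raise ValueError("fewer than two non-empty FST bins")
    F, p = sps.f_oneway(*groups)
    r = correlate(fst, lnv)
    return {"group_means": means, "group_ns": ns, "bins": labels,
            "F": float(F), "p": float(p), "pearson_r": r}


# ---------------------------------------------------------------------------
# Variant-effect regression and SNP/indel comparison

def effect_regression(lnv: pd.Series | np.ndarray,
                      consequence: pd.Series | np.ndarray,
                      min_count: int = 1000) -> dict:
    """OLS of ln(v) on consequence category.

    Categories with fewer than ``min_count`` variants are removed. Reported
    per-category estimates and 95% CIs come from the no-intercept (cell
    means) parameterisation; the overall F and p come from the equivalent
    with-intercept model.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"lnv": np.asarray(lnv, dtype=float),
                       "cat": np.asarray(consequence, dtype=object)})
    df = df.dropna()
    counts = df["cat"].value_counts()
    keep = counts.index[counts >= min_count]
    df = df[df["cat"].isin(keep)]
    if df["cat"].nunique() < 2:
        raise ValueError("fewer than two consequence categories remain")
    X = pd.get_dummies(df["cat"], dtype=float)
    fit = sm.OLS(df["lnv"].to_numpy(), X.to_numpy()).fit()
    ci = fit.conf_int()
    per_cat = pd.DataFrame({
        "category": X.columns, "estimate": fit.params,
        "lo95": ci[:, 0], "hi95": ci[:, 1],
        "n": [int(counts[c]) for c in X.columns],
    }).reset_index(drop=True)
    Xi = sm.add_constant(X.to_numpy()[:, 1:])
    fit_i = sm.OLS(df["lnv"].to_numpy(), Xi).fit()
    return {"per_category": per_cat, "F": float(fit_i.fvalue),
            "p": float(fit_i.f_pvalue), "n_used": len(df)}


def variant_type(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; length change -> indel.

    Equal-length multi-base substitutions (MNPs) are neither and are
    excluded from the SNP/indel comparison.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(ref) != len(alt):
        return "indel"
    return "MNP"


def snp_indel_test(lnv: pd.Series | np.ndarray, ref: pd.Series,
                   alt: pd.Series) -> dict:
    """Mann-Whitney U comparison of ln(v) between SNPs and indels.

    Two-sided, normal approximation with tie correction. Raises if either
    type is absent.
    """
    lnv = np.asarray(lnv, dtype=float)
    types = np.array([variant_type(r, a) for r, a in zip(ref, alt)])
    n_mnp = int((types == "MNP").sum())
    if n_mnp:
        log.info("snp_indel_test: excluded %d MNP loci", n_mnp)
    ok = np.isfinite(lnv)
    snp = lnv[ok & (types == "SNP")]
    indel = lnv[ok & (types == "indel")]
    if len(snp) == 0 or len(indel) == 0:
        raise ValueError("both SNPs and indels must be present")
    u, p = sps.mannwhitneyu(snp, indel, alternative="two-sided",
                            method="asymptotic")
    return {"snp_mean": float(snp.mean()), "snp_sd": float(snp.std(ddof=1)),
            "indel_mean": float(indel.mean()),
            "indel_sd": float(indel.std(ddof=1)),
            "n_snp": len(snp), "n_indel": len(indel),
            "U": float(u), "p": float(p)}


# ---------------------------------------------------------------------------
# Recombination categories

def classify_recomb(recomb_map: pd.DataFrame,
                    hotspot_list: pd.DataFrame | None = None,
                    coldspot_min_run: int = 3,
                    sd_mult: float = 2.5,
                    variants: pd.DataFrame | None = None) -> dict:
    """Per-bin (and optionally per-variant) recombination categories.

    Hotspot: bin count exceeds mean + ``sd_mult``·SD in *both* sires (or the
    bin appears in ``hotspot_list`` with columns chrom, bin_start).
    Coldspot: bin inside a maximal run of >= ``coldspot_min_run`` consecutive
    zero-count bins in *either* sire. Hotspot wins conflicts (flagged).
    Variants falling outside mapped bins are categorised "other".
    """
    m = recomb_map.reset_index(drop=True)
    for col in ("chrom", "bin_start", "bin_end",
                "crossovers_sire1", "crossovers_sire2"):
        if col not in m.columns:
            raise ValueError(f"malformed recombination map: missing {col}")

    if hotspot_list is not None:
        keys = set(zip(hotspot_list["chrom"], hotspot_list["bin_start"]))
        hot = np.array([(c, s) in keys for c, s in
                        zip(m["chrom"], m["bin_start"])])
    else:
        hot = np.ones(len(m), dtype=bool)
        for col in ("crossovers_sire1", "crossovers_sire2"):
            x = m[col].to_numpy(dtype=float)
            hot &= x > x.mean() + sd_mult * x.std(ddof=1)

    cold = np.zeros(len(m), dtype=bool)
    for col in ("crossovers_sire1", "crossovers_sire2"):
        for _, grp in m.groupby("chrom", sort=False):
            x = grp[col].to_numpy(dtype=float)
            i = 0
            while i < len(x):
                if x[i] == 0:
                    j = i
                    while j < len(x) and x[j] == 0:
                        j += 1
                    if j - i >= coldspot_min_run:
                        cold[grp.index[i:j]] = True
                    i = j
                else:
                    i += 1

    conflict = hot & cold
    if conflict.any():
        log.warning("classify_recomb: %d bins both hotspot and coldspot; "
                    "hotspot takes precedence", int(conflict.sum()))
    category = np.where(hot, "hotspot", np.where(cold, "coldspot", "other"))
    out = {"bins": m.assign(category=category)}

    if variants is not None:
        lookup = {}
        for row, cat in zip(m.itertuples(), category):
            lookup.setdefault(row.chrom, []).append(
                (row.bin_start, row.bin_end, cat))
        vcats = []
        n_uncov = 0
        for row in variants.itertuples():
            cat = None
            for start, end, c in lookup.get(row.chrom, ()):
                # bins are 0-based half-open; pos is 1-based
                if start < row.pos <= end:
                    cat = c
                    break
            if cat is None:
                n_uncov += 1
                cat = "other"
            vcats.append(cat)
        if n_uncov:
            log.warning("classify_recomb: %d variants outside mapped bins "
                        "categorised 'other'", n_uncov)
        out["variant_category"] = pd.Series(vcats, index=variants.index)
    return out


def recomb_category_regression(response: pd.Series | np.ndarray,
                               category: pd.Series | np.ndarray) -> dict:
    """OLS of a response on recombination category with Tukey HSD contrasts."""
    import statsmodels.api as sm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.asarray(response, dtype=float)
    cat = np.asarray(category, dtype=object)
    ok = np.isfinite(y)
    y, cat = y[ok], cat[ok]
    levels = pd.unique(cat)
    if len(levels) < 2:
        raise ValueError("need at least two recombination categories")
    X = pd.get_dummies(pd.Series(cat), dtype=float)
    fit = sm.OLS(y, X.to_numpy()).fit()
    per_cat = pd.DataFrame({"category": X.columns, "estimate": fit.params,
                            "n": X.sum().to_numpy(dtype=int)})
    tk = pairwise_tukeyhsd(y, cat)
    contrasts = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
    Xi = sm.add_constant(X.to_numpy()[:, 1:])
    fit_i = sm.OLS(y, Xi).fit()
    return {"per_category": per_cat, "tukey": contrasts,
            "F": float(fit_i.fvalue), "p": float(fit_i.f_pvalue)}


# ---------------------------------------------------------------------------
# Centre-class chi-square and correlation

def centre_class_chisq(scv_counts: dict[str, int] | pd.Series,
                       all_counts: dict[str, int] | pd.Series,
                       background: str = "all") -> dict:
    """Pearson chi-square (df=2) comparing centre-class frequencies.

    Compares the SCV class counts against either the full variant set
    (``background="all"``, as class counts are printed alongside SCV counts)
    or the non-SCV complement (``background="complement"``).
    """
    scv = pd.Series(scv_counts, dtype=float)
    allv = pd.Series(all_counts, dtype=float).reindex(scv.index)
    if background == "complement":
        other = allv - scv
    elif background == "all":
        other = allv
    else:
        raise ValueError("background must be 'all' or 'complement'")
    table = np.vstack([scv.to_numpy(), other.to_numpy()])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p)}


def correlate(x, y) -> float:
    """Pearson correlation over the pairwise-finite subset (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero-variance input")
    return float(sps.pearsonr(xs, ys)[0])
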