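"""End-to-end orchestration: genotypes + Q matrix in, cline tables out.

`run_pipeline` chains the stages — sample grouping, call-rate filter, source
frequency estimation, credible-interval overlap filter, optional LD thinning
for the hybrid-index stage, hybrid-index MCMC, full and v=1 reduced cline
fits, delta-waic, SCV calling, region pooling (overall and per centre class),
gene mapping and the association statistics — writing one TSV per stage plus
a JSON manifest (config echo, input checksums, per-stage counts) that
suffices to rerun the analysis exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cline, genotypes, hybrid, prep, regions, stats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_approaches"]


@dataclass
class RunConfig:
    """All inputs, thresholds and MCMC settings of one pipeline run."""

    vcf: str
    qmatrix: str
    qmatrix_samples: str
    out_dir: str
    seed: int
    annotation: str | None = None          # TSV chrom,pos,ref,alt,consequence
    gff3: str | None = None
    recomb_map: str | None = None
    breed_labels: str | None = None        # TSV sample,breed (for FST)
    min_breed_n: int = 7
    s0_cluster: int = 0
    s1_cluster: int = 1
    assign_threshold: float = 0.99
    min_call_rate: float = 0.95
    esth_nitt: int = 2000
    esth_burnin: int = 1000
    cline_nitt: int = 5000
    cline_burnin: int = 2000
    lnv_threshold: float = 2.3
    dwaic_threshold: float = -10.0
    centre_lo: float = 0.45
    centre_hi: float = 0.55
    max_gap: int = 50_000
    min_variants: int = 10
    annotation_min_count: int = 1000
    include_source: bool = True
    freq_update: str = "fixed"     # "fixed" | "resample"
    freq_shrink: str = "eb"        # "eb" | "none"
    ld_thin: bool = False
    ld_window_bp: int = 50_000
    ld_max_r2: float = 0.2

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {},
                      "inputs": {}}
    for name in ("vcf", "qmatrix", "annotation", "gff3", "recomb_map",
                 "breed_labels"):
        p = getattr(cfg, name)
        if p:
            try:
                manifest["inputs"][name] = _checksum(p)
            except OSError as e:
                raise RuntimeError(
                    f"pipeline stage 'inputs' failed: {e}") from e

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return deco

    # --- prep ---------------------------------------------------------------
    @stage("prep")
    def _prep():
        gm = genotypes.read_vcf(cfg.vcf)
        q = genotypes.read_qmatrix(cfg.qmatrix, cfg.qmatrix_samples)
        assign = genotypes.assign_populations(q, cfg.s0_cluster, cfg.s1_cluster,
                                              cfg.assign_threshold)
        assign.validate()
        gm = genotypes.filter_call_rate(gm, cfg.min_call_rate)
        gm, freqs = prep.estimate_source_freqs(gm, assign)
        freqs_ret, gm_ret = prep.filter_ci_overlap(freqs, gm)
        if cfg.freq_shrink == "eb":
            freqs_ret = prep.eb_shrink_freqs(freqs_ret)
        elif cfg.freq_shrink != "none":
            raise ValueError("freq_shrink must be 'eb' or 'none'")
        return gm, assign, freqs, freqs_ret, gm_ret

    gm, assign, freqs, freqs_ret, gm_ret = _prep
    assign.as_series().rename_axis("sample").to_frame().to_csv(
        out / "assignments.tsv", sep="\t")
    freqs.to_tsv(out / "source_freqs.tsv")
    manifest["stages"]["prep"] = {
        "n_samples": gm.n_samples, "n_loci_callrate": gm.n_loci,
        "n_loci_retained": gm_ret.n_loci,
        "n_s0": len(assign.ids("S0")), "n_s1": len(assign.ids("S1")),
        "n_test": len(assign.ids("TEST"))}

    # --- hybrid index --------------------------------------------------------
    @stage("esth")
    def _esth():
        gm_h, fr_h = gm_ret, freqs_ret
        if cfg.ld_thin:
            thinned = genotypes.ld_thin(gm_ret, cfg.ld_window_bp, cfg.ld_max_r2)
            keep = gm_ret.loci["id"].isin(set(thinned.loci["id"])).to_numpy()
            gm_h = gm_ret.subset_loci(keep)
            fr_h = prep.SourceFreqs(
                freqs_ret.table.loc[keep].reset_index(drop=True))
        return hybrid.esth(gm_h, fr_h, assign, nitt=cfg.esth_nitt,
                           burnin=cfg.esth_burnin, seed=cfg.seed)

    hyb = _esth
    hyb.to_tsv(out / "hybrid_index.tsv")
    manifest["stages"]["esth"] = {"n_samples": len(hyb.table),
                                  "nitt": cfg.esth_nitt,
                                  "burnin": cfg.esth_burnin}

    # --- cline fits ----------------------------------------------------------
    @stage("cline")
    def _cline():
        full = cline.fit_clines(gm_ret, freqs_ret, hyb, assign,
                                nitt=cfg.cline_nitt, burnin=cfg.cline_burnin,
                                include_source=cfg.include_source,
                                freq_update=cfg.freq_update,
                                freq_seed=cfg.seed + 9, seed=cfg.seed + 1)
        red = cline.fit_clines(gm_ret, freqs_ret, hyb, assign,
                               nitt=cfg.cline_nitt, burnin=cfg.cline_burnin,
                               include_source=cfg.include_source,
                               freq_update=cfg.freq_update,
                               freq_seed=cfg.seed + 9,
                               fix_v=True, seed=cfg.seed + 2)
        return cline.compare_models(full, red)

    merged = _cline
    merged.to_csv(out / "cline_fits.tsv", sep="\t", index=False)
    manifest["stages"]["cline"] = {"n_loci": len(merged),
                                   "nitt": cfg.cline_nitt,
                                   "burnin": cfg.cline_burnin}

    # --- SCV and regions -----------------------------------------------------
    @stage("scv")
    def _scv():
        scv = regions.identify_scv(merged, cfg.lnv_threshold,
                                   cfg.dwaic_threshold)
        regs = regions.pool_regions(scv, cfg.max_gap, cfg.min_variants)
        regs_by_c = regions.pool_regions_by_centre(scv, cfg.max_gap,
                                                   cfg.min_variants)
        return scv, regs, regs_by_c

    scv, regs, regs_by_c = _scv
    gene_info = {}
    if cfg.gff3:
        genes = regions.read_gff3_genes(cfg.gff3)
        gene_info = regions.map_genes(scv, genes, regs)
        scv = scv.assign(genes=gene_info["scv_genes"])
    scv.to_csv(out / "scv.tsv", sep="\t", index=False)
    regions.regions_to_frame(regs).to_csv(out / "regions.tsv", sep="\t",
                                          index=False)
    regions.regions_to_bed(regs, out / "regions.bed")
    all_by_c = [r for lst in regs_by_c.values() for r in lst]
    regions.regions_to_frame(all_by_c).to_csv(
        out / "regions_by_centre.tsv", sep="\t", index=False)
    manifest["stages"]["scv"] = {
        "n_scv": len(scv), "n_regions": len(regs),
        "n_regions_by_centre": {k: len(v) for k, v in regs_by_c.items()},
        "frac_scv_in_genes": gene_info.get("frac_scv_in_genes")}

    # --- association stats ---------------------------------------------------
    assoc: dict = {}
    ok_classes = merged["c_mean"].notna()
    all_classes = pd.Series(
        [regions.classify_centre(c, cfg.centre_lo, cfg.centre_hi)
         for c in merged.loc[ok_classes, "c_mean"]]).value_counts()
    scv_classes = scv["centre_class"].value_counts() if len(scv) else None
    if scv_classes is not None and len(scv_classes) == 3:
        assoc["centre_class_chisq"] = stats.centre_class_chisq(
            scv_classes.reindex(regions.CENTRE_CLASSES, fill_value=0),
            all_classes.reindex(regions.CENTRE_CLASSES, fill_value=0))

    if cfg.annotation:
        @stage("annotation")
        def _annot():
            ann = pd.read_csv(cfg.annotation, sep="\t")
            key = ["chrom", "pos", "ref", "alt"]
            ann["chrom"] = ann["chrom"].astype(str)
            joined = merged.assign(chrom=merged["chrom"].astype(str)).merge(
                ann, on=key, how="inner")
            res = {}
            try:
                res["effect_regression"] = {
                    k: (v if not isinstance(v, pd.DataFrame) else
                        v.to_dict("records"))
                    for k, v in stats.effect_regression(
                        joined["lnv_mean"], joined["consequence"],
                        cfg.annotation_min_count).items()}
            except ValueError as e:
                log.warning("effect regression skipped: %s", e)
            try:
                res["snp_indel"] = stats.snp_indel_test(
                    joined["lnv_mean"], joined["ref"], joined["alt"])
            except ValueError as e:
                log.warning("snp/indel test skipped: %s", e)
            return res
        assoc.update(_annot)
    else:
        log.info("no annotation input; variant-effect stage skipped")

    if cfg.breed_labels:
        @stage("fst")
        def _fst():
            br = pd.read_csv(cfg.breed_labels, sep="\t")
            counts = br["breed"].value_counts()
            keep = counts.index[counts >= cfg.min_breed_n]
            br = br[br["breed"].isin(keep)]
            labels = pd.Series(br["breed"].to_numpy(),
                               index=br["sample"].astype(str))
            labels = labels[labels.index.isin(gm_ret.sample_ids)]
            fst = stats.weir_fst_multipop(gm_ret, labels)
            fst.to_csv(out / "fst.tsv", sep="\t", index=False)
            joined = merged.merge(fst[["chrom", "pos", "ref", "alt",
                                       "fst_clamped"]],
                                  on=["chrom", "pos", "ref", "alt"])
            res = {"n_breeds": int(len(keep)),
                   "r_fst_lnv": stats.correlate(joined["fst_clamped"],
                                                joined["lnv_mean"])}
            try:
                an = stats.fst_group_anova(joined["fst_clamped"],
                                           joined["lnv_mean"])
                res["anova"] = {k: v for k, v in an.items()
                                if k != "pearson_r"}
            except ValueError as e:
                log.warning("FST-group ANOVA skipped: %s", e)
            return res
        assoc["fst"] = _fst

    if cfg.recomb_map:
        @stage("recomb")
        def _recomb():
            rmap = pd.read_csv(cfg.recomb_map, sep="\t")
            rmap["chrom"] = rmap["chrom"].astype(str)
            cats = stats.classify_recomb(
                rmap, variants=merged.assign(chrom=merged["chrom"].astype(str)))
            try:
                reg = stats.recomb_category_regression(
                    merged["lnv_mean"], cats["variant_category"])
            except ValueError as e:
                log.warning("recombination-category regression skipped: %s", e)
                return {"skipped": str(e)}
            return {"per_category": reg["per_category"].to_dict("records"),
                    "F": reg["F"], "p": reg["p"]}
        assoc["recomb_regression"] = _recomb
    manifest["stages"]["assoc"] = {k: True for k in assoc}

    with open(out / "association.json", "w") as fh:
        json.dump(assoc, fh, indent=2, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def compare_approaches(cline_a: pd.DataFrame, cline_b: pd.DataFrame,
                       scv_a: pd.DataFrame, scv_b: pd.DataFrame,
                       regions_a: list | None = None,
                       regions_b: list | None = None) -> dict:
    """Overlap report between two runs sharing locus keys.

    Counts/percentages of shared SCVs (keyed by chrom,pos,ref,alt), the
    Pearson correlation of ln(v) over shared SCVs and over all shared loci,
    and any-bp region overlap with each run's own denominator.
    """
    key = ["chrom", "pos", "ref", "alt"]

    def _keys(df):
        return set(map(tuple, df[key].itertuples(index=False)))

    shared_loci = cline_a.merge(cline_b, on=key, suffixes=("_a", "_b"))
    if len(shared_loci) == 0:
        log.warning("compare_approaches: no shared loci")
        return {"n_scv_shared": 0}
    ka, kb = _keys(scv_a), _keys(scv_b)
    shared = ka & kb
    scv_shared = shared_loci.merge(
        pd.DataFrame(sorted(shared), columns=key), on=key)

    def _r(df):
        if len(df) < 3:
            return float("nan")
        try:
            return stats.correlate(df["lnv_mean_a"], df["lnv_mean_b"])
        except ValueError:  # too few finite pairs or degenerate input
            return float("nan")

    out = {
        "n_scv_a": len(ka), "n_scv_b": len(kb), "n_scv_shared": len(shared),
        "pct_of_a": 100.0 * len(shared) / len(ka) if ka else float("nan"),
        "pct_of_b": 100.0 * len(shared) / len(kb) if kb else float("nan"),
        "r_lnv_shared_scv": _r(scv_shared),
        "r_lnv_all_shared": _r(shared_loci),
    }
    if regions_a is not None and regions_b is not None:
        n_ov_a = sum(any(ra.chrom == rb.chrom and ra.start <= rb.end
                         and rb.start <= ra.end for rb in regions_b)
                     for ra in regions_a)
        n_ov_b = sum(any(rb.chrom == ra.chrom and rb.start <= ra.end
                         and ra.start <= rb.end for ra in regions_a)
                     for rb in regions_b)
        out.update({
            "n_regions_a": len(regions_a), "n_regions_b": len(regions_b),
            "n_regions_a_overlapping": n_ov_a,
            "n_regions_b_overlapping": n_ov_b,
            "pct_regions_a": (100.0 * n_ov_a / len(regions_a)
                              if regions_a else float("nan")),
            "pct_regions_b": (100.0 * n_ov_b / len(regions_b)
                              if regions_b else float("nan")),
        })
    return out
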