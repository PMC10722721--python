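"""Steep-cline variant calling, centre classification and region pooling.

A variant is a *steep cline variant* (SCV) when ln(v) > 2.3 (clines steeper
than v = 10) and delta_waic < -10, both strict — a deliberately conservative
joint criterion for restricted introgression. SCVs are classified by cline
centre into S1-biased (c <= 0.45), unbiased (0.45 < c < 0.55) and S0-biased
(c >= 0.55) introgression, and pooled into candidate regions wherever
consecutive SCVs on a chromosome lie within 50 kb of each other; regions with
fewer than ten member variants are discarded. Region bounds are the first and
last member positions (no flanking padding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["identify_scv", "classify_centre", "pool_regions",
           "pool_regions_by_centre", "map_genes", "read_gff3_genes",
           "regions_to_bed"]

CENTRE_CLASSES = ("S1_biased", "unbiased", "S0_biased")


def identify_scv(cline_table: pd.DataFrame, lnv_threshold: float = 2.3,
                 dwaic_threshold: float = -10.0) -> pd.DataFrame:
    """Subset of a merged cline table passing both SCV criteria (strict).

    Adds a ``centre_class`` column from :func:`classify_centre`.
    """
    t = cline_table
    ok = (t["lnv_mean"] > lnv_threshold) & (t["delta_waic"] < dwaic_threshold)
    ok &= t["lnv_mean"].notna() & t["delta_waic"].notna()
    scv = t.loc[ok].reset_index(drop=True).copy()
    scv["centre_class"] = [classify_centre(c) for c in scv["c_mean"]]
    log.info("identify_scv: %d of %d loci pass", len(scv), len(t))
    return scv


def classify_centre(c: float, lo: float = 0.45, hi: float = 0.55) -> str:
    """Centre-bias class: c <= lo -> S1_biased, c >= hi -> S0_biased.

    Boundaries are inclusive; a centre below 0.5 means the locus reaches the
    halfway frequency at low hybrid index, i.e. the S1 allele penetrates the
    S0 background (S1-biased introgression).
    """
    if not (0 < c < 1):
        raise ValueError("centre must lie in (0, 1)")
    if c <= lo:
        return "S1_biased"
    if c >= hi:
        return "S0_biased"
    return "unbiased"


@dataclass
class Region:
    chrom: str
    start: int     # position of the first member SCV, 1-based inclusive
    end: int       # position of the last member SCV
    n_scv: int
    mean_lnv: float
    centre_class: str = "any"
    region_id: str = ""
    genes: list[str] | None = None


def pool_regions(scv: pd.DataFrame, max_gap: int = 50_000,
                 min_variants: int = 10,
                 centre_class: str = "any") -> list[Region]:
    """Greedy pooling of sorted SCVs into regions per chromosome.

    A region extends while the gap to the next SCV is strictly below
    ``max_gap``; regions never span chromosomes, and those with fewer than
    ``min_variants`` members are dropped.
    """
    regions: list[Region] = []
    if len(scv) == 0:
        return regions
    t = scv.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, grp in t.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        lnv = grp["lnv_mean"].to_numpy()
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] >= max_gap:
                n = i - start_i
                if n >= min_variants:
                    regions.append(Region(
                        chrom=str(chrom), start=int(pos[start_i]),
                        end=int(pos[i - 1]), n_scv=n,
                        mean_lnv=float(np.mean(lnv[start_i:i])),
                        centre_class=centre_class))
                start_i = i
    for k, r in enumerate(regions):
        r.region_id = f"REG_{k + 1:04d}" if centre_class == "any" \
            else f"REG_{centre_class}_{k + 1:04d}"
    return regions


def pool_regions_by_centre(scv: pd.DataFrame, max_gap: int = 50_000,
                           min_variants: int = 10) -> dict[str, list[Region]]:
    """Apply :func:`pool_regions` separately within each centre class."""
    out: dict[str, list[Region]] = {}
    for cls in CENTRE_CLASSES:
        sub = scv.loc[scv["centre_class"] == cls]
        out[cls] = pool_regions(sub, max_gap, min_variants, centre_class=cls)
    return out


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end, "n_scv": r.n_scv,
        "mean_lnv": r.mean_lnv, "centre_class": r.centre_class,
        "region_id": r.region_id,
        "genes": ",".join(r.genes) if r.genes else "",
    } for r in regions])


def regions_to_bed(regions: list[Region], path: str) -> None:
    """Write regions as BED (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t"
                     f"{r.n_scv}\t{r.centre_class}\n")


# ---------------------------------------------------------------------------
# Gene annotation

def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene features (chrom, start, end, gene) from a GFF3 file.

    Coordinates stay 1-based closed as in GFF3. The gene name is taken from
    the Name attribute, falling back to ID.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}"))
            rows.append((f[0], int(f[3]), int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def map_genes(scv: pd.DataFrame | None, genes: pd.DataFrame,
              regions: list[Region] | None = None) -> dict:
    """Overlap SCVs and regions with gene intervals (inclusive bounds).

    An SCV is "within" a gene iff gene_start <= pos <= gene_end; a region
    overlaps a gene iff the closed intervals intersect. Returns per-SCV gene
    lists, per-gene SCV counts, the fraction of SCVs within genes, and
    annotates ``regions`` in place.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        # interval tree is half-open; +1 makes the closed end inclusive
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, row.gene)
    if scv is not None and len(scv) and not (set(scv["chrom"]) & set(trees)):
        log.warning("map_genes: no shared chromosome names between SCVs "
                    "and annotation")

    result: dict = {}
    if scv is not None:
        gene_lists = []
        counts: dict[str, int] = {}
        for row in scv.itertuples():
            tree = trees.get(row.chrom)
            hits = sorted(iv.data for iv in tree[row.pos]) if tree else []
            gene_lists.append(",".join(hits))
            for g in hits:
                counts[g] = counts.get(g, 0) + 1
        result["scv_genes"] = gene_lists
        result["gene_scv_counts"] = pd.Series(counts, dtype=int).sort_values(
            ascending=False)
        n_in = sum(1 for g in gene_lists if g)
        result["frac_scv_in_genes"] = n_in / len(scv) if len(scv) else float("nan")
    if regions is not None:
        for r in regions:
            tree = trees.get(r.chrom)
            r.genes = sorted({iv.data for iv in tree.overlap(r.start, r.end + 1)}) \
                if tree else []
        result["regions"] = regions
    return result
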