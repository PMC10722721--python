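"""Genotype containers, VCF/Q-matrix IO and sample grouping.

The central container is :class:`GenotypeMatrix`: a samples × loci matrix of
diploid counts of a designated *focal* allele (0/1/2, −1 for missing) plus a
locus table (chrom, pos, ref, alt). The focal allele is ALT at load time; the
frequency-estimation step may re-orient individual loci so that downstream
"allele frequency" always refers to the allele common in source population S1.

Sample grouping follows the admixture-proportion rule used for hybrid-zone
panels: individuals with more than a threshold proportion (default 0.99,
strict) of one source ancestry are the source panels S0 and S1; everything
else is a putative hybrid ("TEST").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING", "GenotypeMatrix", "PopulationAssignment", "QMatrix",
    "read_vcf", "write_vcf", "read_qmatrix", "assign_populations",
    "filter_call_rate", "ld_thin",
]


@dataclass
class GenotypeMatrix:
    """Diploid focal-allele counts for samples × biallelic loci.

    ``G`` is ``int8`` with entries in {0, 1, 2, MISSING}. ``loci`` is a
    DataFrame with columns chrom, pos (1-based), ref, alt, id and
    ``focal_is_alt`` (bool). Loci are sorted by (chrom, pos).
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci")
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if "focal_is_alt" not in self.loci.columns:
            self.loci = self.loci.assign(focal_is_alt=True)
        if (self.loci["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(self.sample_ids,
                              self.loci.iloc[idx].reset_index(drop=True),
                              self.G[:, idx])

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(list(ids), self.loci.copy(), self.G[idx])

    def flip_loci(self, flip: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix with focal allele flipped at loci where ``flip``."""
        flip = np.asarray(flip, dtype=bool)
        G = self.G.copy()
        cols = np.nonzero(flip)[0]
        for j in cols:
            col = G[:, j]
            nm = col != MISSING
            col[nm] = 2 - col[nm]
        loci = self.loci.copy()
        loci.loc[flip, "focal_is_alt"] = ~loci.loc[flip, "focal_is_alt"]
        return GenotypeMatrix(self.sample_ids, loci, G)


@dataclass
class PopulationAssignment:
    """Sample → label in {S0, S1, TEST, EXCLUDED} with provenance."""

    labels: dict[str, str]
    provenance: str = ""

    def ids(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="label")

    def validate(self) -> None:
        for pop in ("S0", "S1"):
            if len(self.ids(pop)) < 2:
                raise ValueError(f"need at least 2 samples in {pop}")


@dataclass
class QMatrix:
    """Admixture proportions: samples × K ancestry clusters."""

    sample_ids: list[str]
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != len(self.sample_ids):
            raise ValueError("Q must be n_samples x K")
        if ((self.Q < 0) | (self.Q > 1)).any():
            raise ValueError("ancestry proportions must lie in [0,1]")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1 (±1e-6)")

    @property
    def k(self) -> int:
        return self.Q.shape[1]


# ---------------------------------------------------------------------------
# VCF IO

def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT-only biallelic records into a :class:`GenotypeMatrix`.

    Multi-allelic records and records with missing REF/ALT are skipped (with
    a logged count). Any genotype with a missing allele is coded missing.
    Focal allele is initialised to ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: no samples / no GT field")
    rows, cols = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.REF or not v.ALT[0] or v.ALT[0] == ".":
            n_skipped += 1
            continue
        g = np.array([a[:2] for a in v.genotypes], dtype=int)
        code = g.sum(axis=1).astype(np.int8)
        code[(g < 0).any(axis=1)] = MISSING
        cols.append(code)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/incomplete records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic records with GT")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    loci["id"] = [f"{c}:{p}:{r}:{a}" for c, p, r, a in rows]
    loci["focal_is_alt"] = True
    G = np.stack(cols, axis=1)
    gm = GenotypeMatrix(samples, loci, G)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(order))):
        gm = gm.subset_loci(order)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (GT only; missing as ``./.``).

    Genotypes are written in terms of REF/ALT regardless of the current
    focal-allele orientation, so a written file re-read with
    :func:`read_vcf` reproduces the original content.
    """
    order = np.lexsort((gm.loci["pos"].to_numpy(), gm.loci["chrom"].to_numpy()))
    chroms = list(dict.fromkeys(gm.loci["chrom"].iloc[order]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clinemap\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        flipped = {0: "1/1", 1: "0/1", 2: "0/0", MISSING: "./."}
        for j in order:
            row = gm.loci.iloc[j]
            table = codes if row["focal_is_alt"] else flipped
            gts = "\t".join(table[int(g)] for g in gm.G[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row.get('id', '.')}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Q matrix and grouping

def read_qmatrix(q_path: str, sample_ids: list[str] | str) -> QMatrix:
    """Read a whitespace-delimited K-column ancestry matrix.

    ``sample_ids`` is either the list of ids (row order) or the path of a
    one-id-per-line sidecar file, since ADMIXTURE's Q output carries none.
    """
    Q = np.loadtxt(q_path, dtype=float, ndmin=2)
    if isinstance(sample_ids, str):
        with open(sample_ids) as fh:
            sample_ids = [ln.strip().split()[0] for ln in fh if ln.strip()]
    if len(sample_ids) != Q.shape[0]:
        raise ValueError("sample id count does not match Q rows")
    return QMatrix(list(sample_ids), Q)


def assign_populations(q: QMatrix, s0_cluster: int, s1_cluster: int,
                       threshold: float = 0.99) -> PopulationAssignment:
    """Threshold-based grouping into source panels and test samples.

    A sample is S0 (resp. S1) iff its ancestry proportion for the
    corresponding cluster strictly exceeds ``threshold``; all other samples
    are TEST.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    if s0_cluster == s1_cluster:
        raise ValueError("source clusters must be distinct")
    for c in (s0_cluster, s1_cluster):
        if not (0 <= c < q.k):
            raise ValueError(f"cluster index {c} out of range for K={q.k}")
    labels = {}
    for i, s in enumerate(q.sample_ids):
        if q.Q[i, s0_cluster] > threshold:
            labels[s] = "S0"
        elif q.Q[i, s1_cluster] > threshold:
            labels[s] = "S1"
        else:
            labels[s] = "TEST"
    prov = (f"threshold>{threshold} on clusters s0={s0_cluster}, "
            f"s1={s1_cluster} of K={q.k}")
    return PopulationAssignment(labels, prov)


# ---------------------------------------------------------------------------
# Locus filters

def filter_call_rate(gm: GenotypeMatrix, min_rate: float = 0.95) -> GenotypeMatrix:
    """Keep loci whose fraction of non-missing genotypes is ≥ ``min_rate``."""
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must lie in (0, 1]")
    rate = (gm.G != MISSING).mean(axis=0)
    keep = rate >= min_rate
    log.info("filter_call_rate: kept %d of %d loci", int(keep.sum()), gm.n_loci)
    return gm.subset_loci(keep)


def ld_thin(gm: GenotypeMatrix, window_bp: int = 50_000,
            max_r2: float = 0.2) -> GenotypeMatrix:
    """Greedy left-to-right r² thinning of loci within a physical window.

    A locus is dropped if its squared genotype-count correlation with any
    *retained* locus within ``window_bp`` upstream exceeds ``max_r2``
    (missing genotypes pairwise-deleted). This is a simple stand-in for more
    elaborate VIF-based pruning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not (0 < max_r2 <= 1):
        raise ValueError("max_r2 must lie in (0, 1]")
    chrom = gm.loci["chrom"].to_numpy()
    pos = gm.loci["pos"].to_numpy()
    G = gm.G
    kept: list[int] = []
    keep_mask = np.zeros(gm.n_loci, dtype=bool)
    for j in range(gm.n_loci):
        drop = False
        for i in reversed(kept):
            if chrom[i] != chrom[j] or pos[j] - pos[i] > window_bp:
                break
            r2 = _pairwise_r2(G[:, i], G[:, j])
            if r2 is not None and r2 > max_r2:
                drop = True
                break
        if not drop:
            kept.append(j)
            keep_mask[j] = True
    log.info("ld_thin: kept %d of %d loci", len(kept), gm.n_loci)
    return gm.subset_loci(keep_mask)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)
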