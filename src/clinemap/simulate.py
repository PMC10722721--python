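"""Synthetic hybrid-zone genotype data with known cline parameters.

The generator is the exact inverse of the cline model fitted by
:mod:`clinemap.cline`: each allele copy of a test individual at locus l is of
S1 ancestry with probability phi(h_i; v_l, c_l) and, conditional on ancestry,
is the focal allele with probability p1_l (S1) or p0_l (S0). Source
individuals draw both copies from their own population frequency. Ancestry is
sampled independently per allele copy — there are no linkage tracts — because
the cline model itself treats allele copies as independent observations.

Defaults emulate a two-source cattle-like admixture panel: strongly divergent
source frequencies (p0 ~ U(0, 0.2), p1 ~ U(0.8, 1)), hybrid indices
uniform on (0.2, 0.95), a small fraction of indel-type loci, and optional
"barrier" loci with steep clines (ln v >> 0) that may be clustered to
exercise region pooling. None of these values comes from a real study design;
they are package choices documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cline import cline_function
from .genotypes import MISSING, GenotypeMatrix, PopulationAssignment, QMatrix

__all__ = ["FreqModel", "BarrierSpec", "SimConfig", "SimTruth",
           "simulate_dataset", "simulate_recomb_map", "qmatrix_from_truth",
           "simulate_annotations"]


@dataclass
class FreqModel:
    """Source allele-frequency distributions.

    Informative loci draw p0 ~ U(p0_range) and p1 ~ U(p1_range); a fraction
    ``uninformative_frac`` of loci draws both frequencies from
    ``uninformative_range`` so their credible intervals overlap.
    """

    p0_range: tuple[float, float] = (0.0, 0.2)
    p1_range: tuple[float, float] = (0.8, 1.0)
    uninformative_frac: float = 0.0
    uninformative_range: tuple[float, float] = (0.3, 0.7)


@dataclass
class BarrierSpec:
    """A block of loci with a non-neutral cline.

    ``fraction`` of all loci get true ln(v) = ``lnv`` and centre ``c``;
    ``clustered`` places them at consecutive positions (``cluster_spacing``
    bp apart) on one chromosome, as a compact barrier region.
    """

    fraction: float
    lnv: float
    c: float = 0.5
    clustered: bool = False
    cluster_spacing: int = 5_000


@dataclass
class SimConfig:
    n_s0: int = 20
    n_s1: int = 20
    n_test: int = 200
    n_loci: int = 1000
    # (chromosome name, locus count, inter-locus spacing bp)
    chrom_layout: list[tuple[str, int, int]] | None = None
    freq_model: FreqModel = field(default_factory=FreqModel)
    h_range: tuple[float, float] = (0.2, 0.95)
    barrier_spec: list[BarrierSpec] = field(default_factory=list)
    indel_frac: float = 0.08
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_s0, self.n_s1, self.n_test, self.n_loci) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if sum(b.fraction for b in self.barrier_spec) > 1 + 1e-12:
            raise ValueError("barrier fractions must sum to at most 1")
        if self.chrom_layout is None:
            self.chrom_layout = [("1", self.n_loci, 1000)]
        if sum(n for _, n, _ in self.chrom_layout) != self.n_loci:
            raise ValueError("chrom_layout locus counts must sum to n_loci")


@dataclass
class SimTruth:
    """True per-locus cline parameters and per-individual hybrid indices."""

    loci: pd.DataFrame        # chrom, pos, p0, p1, lnv, c, is_barrier
    individuals: pd.DataFrame  # sample, label, h

    def write(self, loci_path: str, ind_path: str) -> None:
        self.loci.to_csv(loci_path, sep="\t", index=False)
        self.individuals.to_csv(ind_path, sep="\t", index=False)


_BASES = np.array(list("ACGT"))


def _positions(layout: list[tuple[str, int, int]],
               cluster: np.ndarray | None,
               cluster_spacing: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Locus chrom/pos from the layout; clustered runs get their own spacing."""
    chroms, pos = [], []
    j = 0
    for name, n, spacing in layout:
        p = 0
        for _ in range(n):
            step = spacing
            if cluster is not None and j > 0 and cluster[j] and cluster[j - 1] \
                    and chroms and chroms[-1] == name:
                step = int(cluster_spacing[j])
            p += step
            chroms.append(name)
            pos.append(p)
            j += 1
    return np.array(chroms), np.array(pos, dtype=int)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix,
                                                 PopulationAssignment,
                                                 SimTruth]:
    """Generate genotypes, population labels and the generating truth.

    Identical seeds give byte-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci

    # --- per-locus truth ---------------------------------------------------
    fm = cfg.freq_model
    p0 = rng.uniform(*fm.p0_range, size=L)
    p1 = rng.uniform(*fm.p1_range, size=L)
    n_unin = int(round(fm.uninformative_frac * L))
    unin = np.zeros(L, dtype=bool)
    if n_unin:
        unin_idx = rng.choice(L, size=n_unin, replace=False)
        unin[unin_idx] = True
        p0[unin] = rng.uniform(*fm.uninformative_range, size=n_unin)
        p1[unin] = rng.uniform(*fm.uninformative_range, size=n_unin)

    lnv = np.zeros(L)
    c = np.full(L, 0.5)
    is_barrier = np.zeros(L, dtype=bool)
    clustered = np.zeros(L, dtype=bool)
    spacing_arr = np.zeros(L)
    free = np.ones(L, dtype=bool)
    for spec in cfg.barrier_spec:
        n_b = int(round(spec.fraction * L))
        if n_b == 0:
            continue
        if spec.clustered:
            # one contiguous run inside a single chromosome
            offs = np.cumsum([0] + [n for _, n, _ in cfg.chrom_layout])
            placed = False
            for k in range(len(cfg.chrom_layout)):
                lo, hi = offs[k], offs[k + 1]
                runs = np.nonzero(free[lo:hi])[0]
                if runs.size >= n_b:
                    # first free run long enough
                    start = None
                    count = 0
                    for idx in range(lo, hi):
                        if free[idx]:
                            if start is None:
                                start = idx
                            count += 1
                            if count == n_b:
                                sel = np.arange(start, start + n_b)
                                placed = True
                                break
                        else:
                            start, count = None, 0
                    if placed:
                        break
            if not placed:
                raise ValueError("no contiguous free block for clustered barrier")
            clustered[sel] = True
            spacing_arr[sel] = spec.cluster_spacing
        else:
            avail = np.nonzero(free)[0]
            sel = rng.choice(avail, size=n_b, replace=False)
        lnv[sel] = spec.lnv
        c[sel] = spec.c
        is_barrier[sel] = True
        free[sel] = False

    chroms, pos = _positions(cfg.chrom_layout, clustered, spacing_arr)

    # ref/alt alleles; a fraction of loci are short indels
    ref = rng.choice(_BASES, size=L)
    shift = rng.integers(1, 4, size=L)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    is_indel = rng.uniform(size=L) < cfg.indel_frac
    ins = rng.choice(_BASES, size=L)
    alt = np.where(is_indel, np.char.add(ref.astype("U2"), ins), alt)

    # --- individuals -------------------------------------------------------
    ids = ([f"S0_{i:03d}" for i in range(cfg.n_s0)]
           + [f"S1_{i:03d}" for i in range(cfg.n_s1)]
           + [f"T_{i:03d}" for i in range(cfg.n_test)])
    labels = (["S0"] * cfg.n_s0 + ["S1"] * cfg.n_s1 + ["TEST"] * cfg.n_test)
    h_true = np.concatenate([
        np.zeros(cfg.n_s0), np.ones(cfg.n_s1),
        rng.uniform(*cfg.h_range, size=cfg.n_test)])

    # --- genotypes ---------------------------------------------------------
    n = len(ids)
    G = np.empty((n, L), dtype=np.int8)
    # source panels: both copies from own frequency
    for rows, p in ((slice(0, cfg.n_s0), p0),
                    (slice(cfg.n_s0, cfg.n_s0 + cfg.n_s1), p1)):
        m = G[rows].shape[0]
        draws = rng.uniform(size=(m, 2, L)) < p[None, None, :]
        G[rows] = draws.sum(axis=1)
    # test individuals: ancestry per copy through the cline, then allele
    ht = h_true[cfg.n_s0 + cfg.n_s1:]
    phi = cline_function(ht[:, None], np.exp(lnv)[None, :], c[None, :])
    anc = rng.uniform(size=(cfg.n_test, 2, L)) < phi[:, None, :]
    pa = np.where(anc, p1[None, None, :], p0[None, None, :])
    alleles = rng.uniform(size=(cfg.n_test, 2, L)) < pa
    G[cfg.n_s0 + cfg.n_s1:] = alleles.sum(axis=1)

    if cfg.missing_rate > 0:
        miss = rng.uniform(size=(n, L)) < cfg.missing_rate
        G[miss] = MISSING

    loci = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
        "id": [f"{ch}:{p}:{r}:{a}" for ch, p, r, a in zip(chroms, pos, ref, alt)],
        "focal_is_alt": True,
    })
    gm = GenotypeMatrix(ids, loci, G)
    assign = PopulationAssignment(dict(zip(ids, labels)), "simulated truth")
    truth = SimTruth(
        loci=pd.DataFrame({"chrom": chroms, "pos": pos, "p0": p0, "p1": p1,
                           "lnv": lnv, "c": c, "is_barrier": is_barrier,
                           "uninformative": unin}),
        individuals=pd.DataFrame({"sample": ids, "label": labels, "h": h_true}),
    )
    return gm, assign, truth


def qmatrix_from_truth(truth: SimTruth, k: int = 3, noise: float = 0.002,
                       seed: int = 0) -> QMatrix:
    """ADMIXTURE-style K-cluster Q matrix consistent with the true labels.

    Cluster 0 carries S0 ancestry (1 − h), cluster 1 carries S1 ancestry
    (h); any further clusters share a small noise mass. Source individuals
    get > 0.99 of their own cluster so threshold grouping recovers the
    simulated labels.
    """
    rng = np.random.default_rng(seed)
    ind = truth.individuals
    n = len(ind)
    Q = np.zeros((n, k))
    for i, (lab, h) in enumerate(zip(ind["label"], ind["h"])):
        if lab in ("S0", "S1"):
            main = rng.uniform(0.992, 0.998)
            rest = rng.uniform(0.1, 1.0, size=k - 1)
            rest *= (1 - main) / rest.sum()
            col = 0 if lab == "S0" else 1
            Q[i, col] = main
            Q[i, [j for j in range(k) if j != col]] = rest
        else:
            spill = rng.uniform(0, noise * (k - 2)) if k > 2 else 0.0
            Q[i, 0] = (1 - h) * (1 - spill)
            Q[i, 1] = h * (1 - spill)
            if k > 2:
                rest = rng.uniform(0.1, 1.0, size=k - 2)
                Q[i, 2:] = spill * rest / rest.sum()
    Q /= Q.sum(axis=1, keepdims=True)
    return QMatrix(list(ind["sample"]), Q)


_CONSEQUENCES = [
    ("intergenic_variant", 0.45), ("intron_variant", 0.30),
    ("upstream_gene_variant", 0.08), ("downstream_gene_variant", 0.08),
    ("synonymous_variant", 0.04), ("missense_variant", 0.03),
    ("3_prime_UTR_variant", 0.015), ("non_coding_transcript_exon_variant", 0.005),
]


def simulate_annotations(loci: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random most-severe consequence categories for a locus table.

    Produces the (chrom, pos, ref, alt, consequence) table the association
    stage consumes; category probabilities are loosely genome-like.
    """
    rng = np.random.default_rng(seed)
    cats, probs = zip(*_CONSEQUENCES)
    p = np.array(probs) / sum(probs)
    cons = rng.choice(cats, size=len(loci), p=p)
    return pd.DataFrame({"chrom": loci["chrom"], "pos": loci["pos"],
                         "ref": loci["ref"], "alt": loci["alt"],
                         "consequence": cons})


def simulate_recomb_map(chrom_layout: list[tuple[str, int, int]],
                        hotspot_bins: list[tuple[str, int]] | None = None,
                        coldspot_runs: list[tuple[str, int, int]] | None = None,
                        seed: int = 0, background_rate: float = 8.0,
                        hotspot_count: int = 60,
                        bin_size: int = 1_000_000) -> pd.DataFrame:
    """Two-sire crossover counts per 1-Mb bin with designated features.

    ``hotspot_bins``: (chrom, bin index) bins set to ``hotspot_count`` in
    both sires. ``coldspot_runs``: (chrom, first bin index, run length) runs
    (length >= 3 to qualify downstream) zeroed in sire 1. Background counts
    are Poisson(``background_rate``) conditioned positive, so no accidental
    zero runs arise. Overlapping designations are rejected.
    """
    rng = np.random.default_rng(seed)
    hotspot_bins = hotspot_bins or []
    coldspot_runs = coldspot_runs or []
    rows = []
    for name, n_loci, spacing in chrom_layout:
        span = n_loci * spacing
        n_bins = max(1, -(-span // bin_size))
        for b in range(n_bins):
            rows.append((name, b * bin_size, (b + 1) * bin_size))
    bins = pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end"])

    def _draw(size):
        x = rng.poisson(background_rate, size=size)
        while (x == 0).any():
            x[x == 0] = rng.poisson(background_rate, size=int((x == 0).sum()))
        return x

    bins["crossovers_sire1"] = _draw(len(bins))
    bins["crossovers_sire2"] = _draw(len(bins))

    cold = set()
    for chrom, start, run in coldspot_runs:
        for b in range(start, start + run):
            cold.add((chrom, b))
    hot = set(hotspot_bins)
    if hot & cold:
        raise ValueError("hotspot and coldspot designations overlap")

    index = {(r.chrom, i): j for j, (r, i) in enumerate(
        zip(bins.itertuples(), bins.groupby("chrom").cumcount()))}
    for key in hot:
        if key not in index:
            raise ValueError(f"hotspot bin {key} outside simulated chromosomes")
        j = index[key]
        bins.loc[j, ["crossovers_sire1", "crossovers_sire2"]] = hotspot_count
    for key in cold:
        if key not in index:
            raise ValueError(f"coldspot bin {key} outside simulated chromosomes")
        bins.loc[index[key], "crossovers_sire1"] = 0
    return bins
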