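"""Generate the synthetic hybrid-zone dataset used by the analysis chain.

Writes a VCF, an ADMIXTURE-style Q matrix with sample sidecar, a
recombination map, a consequence-annotation table, a gene annotation and
the generating truth under results/data/. The panel: 20 + 20 source
individuals, 200 admixed individuals (h ~ U(0.2, 0.95)), 4000 loci on two
chromosomes with a small set of steep-cline "barrier" loci, one of them a
clustered block, plus 8% indels and 1% missing genotypes.
"""

from pathlib import Path

import numpy as np

import clinemap as cm

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20_240_101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = [("1", 2500, 20_000), ("2", 1500, 20_000)]
    cfg = cm.SimConfig(
        n_s0=20, n_s1=20, n_test=200, n_loci=4000,
        chrom_layout=layout,
        freq_model=cm.FreqModel(uninformative_frac=0.10),
        barrier_spec=[
            cm.BarrierSpec(0.01, 2.7, 0.5),
            cm.BarrierSpec(0.005, 2.5, 0.35),
            cm.BarrierSpec(0.005, 2.5, 0.65),
            cm.BarrierSpec(15 / 4000, 2.7, 0.5, clustered=True),
        ],
        missing_rate=0.01, seed=SEED)
    gm, assign, truth = cm.simulate_dataset(cfg)

    cm.write_vcf(gm, OUT / "genotypes.vcf")
    q = cm.qmatrix_from_truth(truth, k=3, seed=SEED + 1)
    np.savetxt(OUT / "admixture.Q", q.Q, fmt="%.6f")
    (OUT / "samples.txt").write_text("\n".join(q.sample_ids) + "\n")
    truth.write(OUT / "truth_loci.tsv", OUT / "truth_individuals.tsv")

    ann = cm.simulate_annotations(gm.loci, seed=SEED + 2)
    ann.to_csv(OUT / "annotation.tsv", sep="\t", index=False)

    # pseudo-breeds: admixed samples binned by hybrid index (breeds in a
    # hybrid swarm differ mostly by admixture proportion)
    test = truth.individuals[truth.individuals.label == "TEST"].copy()
    test["breed"] = ("BR" + (np.argsort(np.argsort(test["h"])) * 5
                             // len(test) + 1).astype(str))
    test[["sample", "breed"]].to_csv(OUT / "breeds.tsv", sep="\t",
                                     index=False)

    rmap = cm.simulate_recomb_map(layout,
                                  hotspot_bins=[("1", 3), ("2", 10)],
                                  coldspot_runs=[("1", 20, 4), ("2", 2, 3)],
                                  seed=SEED + 3)
    rmap.to_csv(OUT / "recomb_map.tsv", sep="\t", index=False)

    # genes tiled over both chromosomes so some SCVs fall inside genes
    rng = np.random.default_rng(SEED + 4)
    lines = ["##gff-version 3"]
    gid = 0
    for chrom, n_loci, spacing in layout:
        span = n_loci * spacing
        for start in range(10_000, span - 40_000, 120_000):
            if rng.uniform() < 0.6:
                end = start + int(rng.integers(8_000, 60_000))
                gid += 1
                lines.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\t"
                             f"ID=gene:g{gid};Name=GENE{gid}")
    (OUT / "genes.gff3").write_text("\n".join(lines) + "\n")

    n_bar = int(truth.loci.is_barrier.sum())
    print(f"wrote {gm.n_samples} samples x {gm.n_loci} loci to {OUT}")
    print(f"  barrier loci: {n_bar} (incl. one clustered block of 15)")
    print(f"  genes: {gid}; recombination bins: {len(rmap)}")


if __name__ == "__main__":
    main()
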