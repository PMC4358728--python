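"""Nucleotide-fixation screening with coding effects.

Builds ML consensus genotypes from the likelihoods, screens for loci with
a unique genotype in cultivars (and, reciprocally, in wild), localizes
them to the called sweep regions, classifies coding effects against the
toy gene models, and summarizes the wild-frequency spectrum of
cultivar-fixed variants.
"""

import numpy as np
import pandas as pd
from common import DATA, RESULTS
from pyfaidx import Fasta

from soysweep import diversity, fixation
from soysweep.genotype import assign_ml_genotypes, read_manifest, read_vcf
from soysweep.scan import SweepRegion


def load_regions() -> list[SweepRegion]:
    out = []
    for line in (RESULTS / "sweep_regions.bed").read_text().splitlines():
        if not line.strip():
            continue
        p = line.split("\t")
        out.append(SweepRegion(p[0], int(p[1]), int(p[2]), p[3], int(p[4]), float(p[5])))
    return out


def main() -> None:
    gm, gl, _ = read_vcf(DATA / "variants.vcf")
    manifest = read_manifest(DATA / "populations.tsv")
    regions = load_regions()

    ml = assign_ml_genotypes(gl)
    consensus = ml.matrix
    complete = np.all(consensus.calls >= 0, axis=0)
    consensus = consensus.take_sites(complete)
    print(f"consensus: {consensus.n_sites:,} sites "
          f"({ml.n_ties} likelihood ties, {int((~complete).sum())} dropped)")

    genome = Fasta(str(DATA / "genome.fa"))
    models = fixation.read_gene_models(DATA / "genes.gff3")

    for focal, other, tag in (("cultivated", "wild", "cultivated"),
                              ("wild", "cultivated", "wild")):
        loci = fixation.detect_fixations(consensus, manifest, focal, other,
                                         regions=regions)
        fixation.classify_loci(loci, models, genome)
        table = fixation.loci_to_table(loci)
        table.to_csv(RESULTS / f"fixations_{tag}.tsv", sep="\t", index=False)
        in_sweep = int(table["in_sweep"].sum()) if len(table) else 0
        nonsyn = int((table["effect"] == "nonsynonymous").sum()) if len(table) else 0
        syn = int((table["effect"] == "synonymous").sum()) if len(table) else 0
        print(f"fixed in {tag}: {len(loci):,} loci ({in_sweep:,} inside sweep "
              f"regions; coding effects {nonsyn} non-synonymous / {syn} synonymous)")
        if tag == "cultivated":
            tiling = diversity.sliding_windows(
                {c: 1_000_000 for c in dict.fromkeys(gm.chrom.astype(str))},
                20_000, 20_000,
            )
            density = fixation.fixation_density(loci, regions, tiling)
            density.to_csv(RESULTS / "fixation_density.tsv", sep="\t", index=False)
            s = fixation.density_summary(density)
            print(f"  density per 20 kb window: {s['sweep_mean']:.1f} in sweeps "
                  f"vs {s['genome_mean']:.1f} genome-wide (x{s['ratio']:.2f})")
            spectrum = fixation.wild_frequency_of_fixed(gm, manifest, loci)
            pd.DataFrame(
                {"alt_count": np.arange(len(spectrum)), "n_sites": spectrum}
            ).to_csv(RESULTS / "fixed_sfs_wild.tsv", sep="\t", index=False)
            print(f"  wild-frequency spectrum of fixed loci written "
                  f"({spectrum.sum():,} loci)")


if __name__ == "__main__":
    main()
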