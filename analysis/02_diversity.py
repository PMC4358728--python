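"""Windowed diversity, the reduction series, rarefaction and SFS.

Computes 20 kb / 2 kb sliding-window θπ, θw and Tajima's D per population,
the genome-average diversity series wild → landrace → elite with the
retention/reduction percentages, SNV accumulation curves, and the wild
site-frequency spectrum. Tables land under results/.
"""

import numpy as np
import pandas as pd
from common import DATA, RESULTS, SEED

from soysweep import diversity
from soysweep.genotype import read_manifest, read_vcf, subset_population
from soysweep.scan import diversity_reduction_summary


def main() -> None:
    gm, _, _ = read_vcf(DATA / "variants.vcf")
    manifest = read_manifest(DATA / "populations.tsv")
    chrom_lengths = {c: 1_000_000 for c in dict.fromkeys(gm.chrom.astype(str))}
    windows = diversity.sliding_windows(chrom_lengths)
    span = sum(chrom_lengths.values())

    pis = {}
    for group in ("wild", "landrace", "elite", "cultivated"):
        sub = subset_population(gm, manifest, group)
        stats = diversity.window_stats(sub, windows)
        stats.to_csv(RESULTS / f"diversity_{group}.tsv", sep="\t", index=False)
        pis[group] = diversity.mean_theta_pi(sub, span)
        print(f"theta_pi[{group}] = {pis[group]:.3e} per nucleotide "
              f"({len(stats)} windows)")

    summary = diversity_reduction_summary(
        pis["wild"], pis["landrace"], pis["elite"], pis["cultivated"]
    )
    print(f"cultivars retain {summary['retention_pct']:.1f}% of wild diversity; "
          f"reduction {summary['domestication_reduction_pct']:.1f}% in "
          f"domestication, a further {summary['improvement_reduction_pct']:.1f}% "
          "in improvement")
    pd.DataFrame([summary]).to_csv(
        RESULTS / "diversity_reduction.tsv", sep="\t", index=False
    )

    for group in ("wild", "cultivated", "elite"):
        n = len(manifest.samples_for(group))
        ks = sorted(set(np.linspace(1, n, min(n, 12)).astype(int)))
        curve = diversity.snv_accumulation(gm, manifest, group, ks, reps=50, seed=SEED)
        curve.to_csv(RESULTS / f"rarefaction_{group}.tsv", sep="\t", index=False)
        sat = curve["mean"].iloc[-1]
        k95 = curve.loc[curve["mean"] >= 0.95 * sat, "k"].iloc[0]
        print(f"rarefaction[{group}]: {int(sat):,} SNVs at k={n}; "
              f"95% reached by k={k95}")

    wild = subset_population(gm, manifest, "wild")
    spectrum = diversity.sfs(wild)
    pd.DataFrame({"alt_count": np.arange(len(spectrum)), "n_sites": spectrum}).to_csv(
        RESULTS / "sfs_wild.tsv", sep="\t", index=False
    )
    print(f"wild SFS written ({spectrum.sum():,} sites; "
          f"{100 * spectrum[1] / max(spectrum[1:].sum(), 1):.0f}% singleton class)")


if __name__ == "__main__":
    main()
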