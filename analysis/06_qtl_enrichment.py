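"""QTL narrowing by fixation-bearing sweep regions, and gene enrichment.

Intersects the toy QTL catalogue with sweep regions that carry at least
one nucleotide fixation, reports the input vs retained footprint, then
tests gene categories for over-representation among sweep genes with
Fisher's exact test, a permutation test, and BH FDR.
"""

import pandas as pd
from common import DATA, RESULTS, SEED

from soysweep import fixation, qtl


def main() -> None:
    regions = []
    for line in (RESULTS / "sweep_regions.bed").read_text().splitlines():
        p = line.split("\t")
        from soysweep.scan import SweepRegion

        regions.append(SweepRegion(p[0], int(p[1]), int(p[2]), p[3], int(p[4]), float(p[5])))
    loci = pd.read_csv(RESULTS / "fixations_cultivated.tsv", sep="\t")
    has_fix = {
        (r.chrom, r.start, r.end): bool(
            ((loci["chrom"] == r.chrom)
             & (loci["pos"] >= r.start + 1)
             & (loci["pos"] <= r.end)).any()
        )
        for r in regions
    }

    qtls = qtl.read_qtl_bed(DATA / "qtl.bed")
    narrowed, summary = qtl.narrow_qtl(qtls, regions, has_fix)
    narrowed.to_csv(RESULTS / "qtl_narrowed.tsv", sep="\t", index=False)
    print(f"QTL catalogue: {int(summary['n_qtl_input'])} intervals, "
          f"{summary['input_mb']:.2f} Mb -> narrowed to "
          f"{summary['retained_mb']:.3f} Mb across "
          f"{int(summary['n_qtl_retained'])} QTLs "
          f"({int(summary['n_traits_retained'])} traits)")

    models = fixation.read_gene_models(DATA / "genes.gff3")
    spans = {
        m.gene_id: (m.chrom, min(s for s, e, _ in m.cds) - 1, max(e for s, e, _ in m.cds))
        for m in fixation.longest_transcript_per_gene(models)
    }
    background = set(spans)
    selected = qtl.genes_in_intervals(
        spans, [(r.chrom, r.start, r.end) for r in regions]
    )
    categories = qtl.read_gene_categories(DATA / "gene_categories.tsv")
    enr = qtl.fisher_enrichment(selected, background, categories)
    perm = qtl.permutation_enrichment(
        selected, background, categories, reps=10_000, seed=SEED
    )
    enr = enr.merge(perm[["category", "p_perm"]], on="category", how="left")
    enr.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    print(f"enrichment over {len(background)} background genes, "
          f"{len(selected)} selected:")
    for row in enr.itertuples(index=False):
        print(f"  {row.category}: k={row.k}/{row.m}, odds={row.odds_ratio:.2f}, "
              f"Fisher P={row.p_fisher:.3g}, permutation P={row.p_perm:.3g}, "
              f"q={row.q_bh:.3g}")


if __name__ == "__main__":
    main()
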