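"""Sweep scans for the two transitions and recovery against truth.

Domestication: cultivated/wild θπ-ratio + cultivated Tajima's D, joint
Z tests at P < 0.05. Improvement: elite-branch PBS on Hudson Fst at
Bonferroni-corrected P < 0.001. Selected windows are merged into regions
and compared with the generator's injected sweeps.
"""

import pandas as pd
from common import DATA, RESULTS, SEED, study_config

from soysweep import diversity, scan
from soysweep.genotype import read_manifest, read_vcf
from soysweep.pipeline import sweep_recovery
from soysweep.simulate import simulate_populations


def main() -> None:
    gm, _, _ = read_vcf(DATA / "variants.vcf")
    manifest = read_manifest(DATA / "populations.tsv")
    truth = simulate_populations(study_config(SEED)).truth  # same seed, same truth
    chrom_lengths = {c: 1_000_000 for c in dict.fromkeys(gm.chrom.astype(str))}
    windows = diversity.sliding_windows(chrom_lengths)

    dom = scan.domestication_scan(gm, manifest, windows)
    dom.to_csv(RESULTS / "scan_domestication.tsv", sep="\t", index=False)
    regions_dom = scan.merge_windows(dom, "domestication")
    print(f"domestication: {int(dom['selected'].sum())} of {len(dom)} windows "
          f"selected -> {len(regions_dom)} regions, "
          f"{sum(r.span for r in regions_dom) / 1e6:.3f} Mb")

    imp = scan.improvement_scan(gm, manifest, windows)
    imp.to_csv(RESULTS / "scan_improvement.tsv", sep="\t", index=False)
    regions_imp = scan.merge_windows(imp, "improvement")
    print(f"improvement:   {int(imp['selected'].sum())} of {len(imp)} windows "
          f"selected -> {len(regions_imp)} regions, "
          f"{sum(r.span for r in regions_imp) / 1e6:.3f} Mb")

    regions = regions_dom + regions_imp
    scan.regions_to_bed(regions).to_csv(
        RESULTS / "sweep_regions.bed", sep="\t", index=False, header=False
    )
    rec = sweep_recovery(truth.swept_regions, regions)
    print(f"recovery vs injected truth: domestication "
          f"{100 * rec['domestication']:.0f}%, improvement "
          f"{100 * rec['improvement']:.0f}%")
    pd.DataFrame([rec]).to_csv(RESULTS / "sweep_recovery.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
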