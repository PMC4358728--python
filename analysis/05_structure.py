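"""Population structure: PCA and a bootstrap-supported NJ tree.

Runs Patterson-normalized PCA and builds an allele-sharing-distance
neighbor-joining tree with site-resampling bootstrap (100 replicates here;
the library supports the full 1,000). Sites are evenly thinned to keep the
tree stage fast.
"""

import numpy as np
import pandas as pd
from common import DATA, RESULTS, SEED

from soysweep import structure
from soysweep.genotype import read_manifest, read_vcf


def main() -> None:
    gm, _, _ = read_vcf(DATA / "variants.vcf")
    manifest = read_manifest(DATA / "populations.tsv")
    idx = np.unique(np.linspace(0, gm.n_sites - 1, 5000).astype(int))
    thin = gm.take_sites(idx)

    coords, evr = structure.pca(thin, n_components=5)
    table = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    table["sample"] = gm.samples
    table["population"] = [manifest.labels[s] for s in gm.samples]
    table.to_csv(RESULTS / "pca.tsv", sep="\t", index=False)
    print(f"PCA: PC1 explains {100 * evr[0]:.1f}%, PC2 {100 * evr[1]:.1f}% "
          f"of variance ({thin.n_sites} sites)")
    pc1_wild = table.loc[table["population"] == "wild", "PC1"]
    pc1_cult = table.loc[table["population"] != "wild", "PC1"]
    sep = pc1_wild.min() > pc1_cult.max() or pc1_wild.max() < pc1_cult.min()
    print(f"PC1 separates wild from cultivated: {sep}")

    dm = structure.pairwise_distance(thin)
    (RESULTS / "distances.phylip").write_text(dm.to_phylip())
    tree = structure.bootstrap_support(thin, reps=100, seed=SEED)
    (RESULTS / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    split = frozenset(s for s in gm.samples if manifest.labels[s] != "wild")
    support = _support_of(tree, split)
    print(f"NJ tree written; wild/cultivated split bootstrap support: "
          f"{support if support is not None else 'split not monophyletic'}")


def _support_of(tree, side):
    total = frozenset(tree.leaves())
    anchor = min(total)
    side = side if anchor not in side else total - side
    found = []

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        canon = below if anchor not in below else total - below
        if canon == side and node.support is not None:
            found.append(node.support)
        return below

    walk(tree)
    return found[0] if found else None


if __name__ == "__main__":
    main()
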