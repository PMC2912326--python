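#!/usr/bin/env python
"""Draw the genome map: IBS distances on each call-rate variant, classical
MDS and standardised PCA coordinates, and population-level and
individual-level neighbor-joining trees, with a population-separation
summary per variant.

Reads results/callrate_grid/, writes results/genome_map/.
"""

import sys
from pathlib import Path

from popflow import distances, genotype_io, njtree, projection

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    src = BASE / "callrate_grid"
    if not (src / "data0.ped").exists():
        print("run analysis/03_callrate_grid.py first", file=sys.stderr)
        return 1
    out = BASE / "genome_map"
    out.mkdir(parents=True, exist_ok=True)
    for name in ["data0", "data1", "data2", "data3"]:
        mat = genotype_io.read_ped_map(src / f"{name}.ped", src / f"{name}.map")
        dist = distances.distance_matrix(mat, metric="IBS")
        genotype_io.write_distance_phylip(dist, out / f"{name}_ibs.phylip")
        mds = projection.classical_mds(dist, k=5)
        pca = projection.snp_pca(mat, k=5)
        genotype_io.write_embedding_tsv(mds, mat.pop_labels, out / f"{name}_mds.tsv")
        genotype_io.write_embedding_tsv(pca, mat.pop_labels, out / f"{name}_pca.tsv")
        pop_dist = distances.population_centroid_distances(dist, mat.pop_labels)
        tree = njtree.neighbor_joining(pop_dist)
        (out / f"{name}_nj_groups.nwk").write_text(njtree.to_newick(tree) + "\n")
        sep = projection.embedding_separation(mds.coordinates, mat.pop_labels)
        print(f"{name}: {mat.n_markers} markers; MDS separation "
              f"(between-centroid / within-spread) = {sep:.2f}; "
              f"MDS var explained C1+C2 = "
              f"{mds.variance_explained[:2].sum():.2f}")
    print(f"coordinates, PHYLIP matrices and NJ trees under {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
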