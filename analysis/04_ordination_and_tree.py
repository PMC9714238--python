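#!/usr/bin/env python
"""Spatial and tree views of the population distances.

Classical MDS embeds the Rst matrix in two dimensions; neighbor joining
builds the population tree from the Fst matrix and writes it as Newick.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ystrkit.io import read_distance_matrix
from ystrkit.ordination import classical_mds
from ystrkit.tree import neighbor_joining, write_newick

OUT = Path(__file__).resolve().parents[1] / "results"


def load_symmetric(path):
    labels, m = read_distance_matrix(path)
    low = np.tril(m, k=-1)  # p-values live above the diagonal
    return labels, low + low.T


def main() -> None:
    labels, rst = load_symmetric(OUT / "dist_rst.tsv")
    emb = classical_mds(labels, rst, dims=2)
    coords = pd.DataFrame(emb.coordinates, index=labels,
                          columns=["dim1", "dim2"])
    coords.to_csv(OUT / "mds.tsv", sep="\t", index_label="population",
                  float_format="%.6f")
    print(f"wrote {OUT / 'mds.tsv'} (strain {emb.strain:.4f})")
    print(coords.to_string())

    labels_f, fst = load_symmetric(OUT / "dist_fst.tsv")
    tree = neighbor_joining(labels_f, fst)
    nwk = write_newick(tree)
    (OUT / "nj_tree.nwk").write_text(nwk + "\n")
    print(f"wrote {OUT / 'nj_tree.nwk'}")
    print(f"  {nwk}")


if __name__ == "__main__":
    main()
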