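#!/usr/bin/env python
"""Allometric and environmental covariation tests: the five standard
pairings (log centroid size vs shape PC1; temperature vs size; each of
temperature and rainfall vs shape PC1; rainfall vs PC2), fit by simple
OLS and, with the phylogeny's Brownian covariance, by PGLS.

Writes results/{regression_ols.csv, regression_pgls.csv}.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, quantified_shapes

from wingmorph.morphospace import fit_shape_space
from wingmorph.outlines import centroid_size
from wingmorph.regression import regression_table


def main():
    std, X, truth, tree, cfg = quantified_shapes()
    taxa = list(truth.index)
    space = fit_shape_space(X)

    data = pd.DataFrame(
        {
            "pc1": space.scores[:, 0],
            "pc2": space.scores[:, 1],
            "centroid_size": [centroid_size(o) for o in std],
            "mat": truth["mat"],
            "mar": truth["mar"],
        },
        index=taxa,
    )
    for label, table in [
        ("OLS", regression_table(data)),
        ("PGLS", regression_table(data, tree=tree)),
    ]:
        fname = RESULTS / f"regression_{label.lower()}.csv"
        table.to_csv(fname, index=False, float_format="%.6g")
        print(f"{label}:")
        for _, row in table.iterrows():
            star = " *" if row["p"] < 0.05 else ""
            print(f"  {row['test']:38s} R2={row['multiple_r2']:.4f} "
                  f"F={row['F']:.3f} p={row['p']:.3g} "
                  f"slope={row['slope']:+.4g}{star}")


if __name__ == "__main__":
    main()
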