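#!/usr/bin/env python
"""Rank every viable theoretical wing by Pareto rank ratio for the
three-way trade-off (maximize AR, maximize r2hat, minimize median VMS)
and for all three pairwise trade-offs, and band the optimality
landscape into 10 contour levels.

Reads results/grid_landscapes.csv; writes results/optimality.csv and
results/figures/landscape_optimality.png.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, quantified_shapes

from wingmorph.morphospace import build_theoretical_grid, fit_shape_space
from wingmorph.pareto import ObjectiveSpec, optimality_landscape
from wingmorph.pipeline import _plot_landscape


def main():
    records = pd.read_csv(RESULTS / "grid_landscapes.csv")
    viable = records[records["viable"] == 1].reset_index(drop=True)
    spec = ObjectiveSpec()

    land = optimality_landscape(viable, spec)
    out = viable[["cell_id", "pc1", "pc2"]].copy()
    out["f"] = land.forward_rank
    out["b"] = land.reverse_rank
    out["ratio"] = land.rank_ratio
    out["band"] = land.bands
    print(f"three-way trade-off: {land.n_fronts} fronts, "
          f"{int((land.rank_ratio == 1.0).sum())} shapes on the Pareto front")

    for pair in [("AR", "median_vms"), ("AR", "r2hat"), ("r2hat", "median_vms")]:
        sub = optimality_landscape(viable, spec, pairwise=pair)
        out[f"ratio_{pair[0]}_{pair[1]}"] = sub.rank_ratio
        rho = spearmanr(land.rank_ratio, sub.rank_ratio).statistic
        print(f"  pairwise {pair[0]} vs {pair[1]}: rank correlation with "
              f"three-way ratios rho = {rho:+.2f}")

    out.to_csv(RESULTS / "optimality.csv", index=False, float_format="%.6g")

    std, X, truth, tree, cfg = quantified_shapes()
    space = fit_shape_space(X)
    grid = build_theoretical_grid(space)
    full = np.full(grid.n_cells, np.nan)
    full[out["cell_id"].to_numpy()] = out["ratio"].to_numpy()
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    _plot_landscape(
        grid, full, figdir / "landscape_optimality.png", "Pareto rank ratio"
    )


if __name__ == "__main__":
    main()
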