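"""End-to-end orchestration of the wing-morphospace analysis.

Stages, in order: read (or generate) outlines -> standardize/resample ->
EFA + normalization -> PCA shape space -> theoretical grid + viability
screen -> performance metrics (AR, r2hat, FEA median VMS) per viable
cell -> Pareto optimality landscape (three-way plus pairwise) ->
phylomorphospace + K_mult -> OLS/PGLS covariation tables.  Every stage
writes plain-text artifacts into the run directory, and the whole run is
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wingmorph import efa, fea, morphospace, outlines, pareto, performance, phylo
from wingmorph.regression import regression_table

logger = logging.getLogger("wingmorph")

__all__ = ["RunConfig", "run_pipeline", "score_grid"]


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the study's stated settings."""

    out_dir: str = "results/run"
    outline_dir: str | None = None  # directory of per-taxon x,y CSVs
    tree_path: str | None = None  # Newick
    covariates_path: str | None = None  # CSV keyed by taxon label
    # synthetic-data fallback when no outline_dir is given
    n_taxa: int = 60
    seed: int = 0
    # shape quantification
    P: int = 150
    H: int = 9
    # theoretical grid
    n_cols: int = 26
    n_rows: int = 19
    border_frac: float = 0.2
    # FEA
    n_elements: int = 2500
    E: float = 1.0e9
    nu: float = 0.49
    load: float = 0.003
    thickness_frac: float = 0.01  # thickness = frac * sqrt(area) after unit-area scaling
    # comparative analyses
    kmult_iterations: int = 9999
    # performance metrics
    n_stations: int = 200
    pareto_metrics: tuple = ("AR", "r2hat", "median_vms")
    pareto_directions: tuple = ("max", "max", "min")
    make_plots: bool = True


def _quantify(outline, P: int, H: int):
    std = outlines.orient_standard(outline)
    res = outlines.resample_equal_arclength(std, P)
    coeffs = efa.efa_normalize(efa.efa_forward(res, H))
    return res, coeffs


def score_grid(grid, config: RunConfig) -> pd.DataFrame:
    """AR, r2hat and FEA median/mean VMS for every grid cell.

    Non-viable cells carry NaN.  Shapes are rescaled to unit area (and a
    fixed thickness fraction) before meshing so only relative VMS matters.
    """
    n = grid.n_cells
    out = {
        "cell_id": np.arange(n),
        "pc1": grid.cell_scores[:, 0],
        "pc2": grid.cell_scores[:, 1],
        "viable": grid.viable.astype(bool),
        "AR": np.full(n, np.nan),
        "r2hat": np.full(n, np.nan),
        "median_vms": np.full(n, np.nan),
        "mean_vms": np.full(n, np.nan),
    }
    for i in range(n):
        if not grid.viable[i]:
            continue
        shape = outlines.orient_standard(grid.outlines[i])
        out["AR"][i] = performance.aspect_ratio(shape)
        out["r2hat"][i] = performance.radius_second_moment(
            shape, n_stations=config.n_stations
        )
        unit = shape / np.sqrt(outlines.polygon_area(shape))
        mesh = fea.mesh_outline(unit, n_target=config.n_elements)
        res = fea.solve_plate(
            mesh,
            E=config.E,
            nu=config.nu,
            thickness=config.thickness_frac,
            load=config.load,
        )
        out["median_vms"][i] = res.median_vms
        out["mean_vms"][i] = res.mean_vms
    return pd.DataFrame(out)


def _plot_landscape(grid, values, path, title, cmap="Blues"):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        Z = np.asarray(values, dtype=float).reshape(grid.n_rows, grid.n_cols)
        fig, ax = plt.subplots(figsize=(7, 5))
        masked = np.ma.masked_invalid(Z)
        cs = ax.contourf(
            grid.pc1_values, grid.pc2_values, masked, levels=10, cmap=cmap
        )
        fig.colorbar(cs, ax=ax)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(title)
        fig.savefig(path, dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never abort numeric outputs
        logger.warning("plotting failed for %s: %s", title, exc)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    # ---- stage 1: inputs ---------------------------------------------------
    stage("inputs")
    if config.outline_dir is not None:
        paths = sorted(Path(config.outline_dir).glob("*.csv"))
        if len(paths) < 3:
            raise RuntimeError("inputs: need >= 3 outlines")
        taxa = [p.stem for p in paths]
        raw = [outlines.read_outline(p) for p in paths]
        covariates = (
            pd.read_csv(config.covariates_path, index_col=0)
            if config.covariates_path
            else None
        )
    else:
        from wingmorph.synth import SimulationConfig, gen_wing_set, gen_tree

        sim = SimulationConfig(n_taxa=config.n_taxa, seed=config.seed)
        raw, truth = gen_wing_set(sim)
        taxa = list(truth.index)
        covariates = truth
        truth.to_csv(out / "ground_truth.csv")
    tree = None
    if config.tree_path is not None:
        tree = phylo.read_newick(config.tree_path)
    elif config.outline_dir is None:
        from wingmorph.synth import gen_tree

        tree = gen_tree(len(taxa), seed=config.seed)
        phylo.write_newick(tree, out / "tree.nwk")

    # ---- stage 2: shape quantification ------------------------------------
    stage("efa")
    resampled, coeff_rows = [], []
    for o in raw:
        res, coeffs = _quantify(o, config.P, config.H)
        resampled.append(res)
        coeff_rows.append(efa.coeffs_to_vector(coeffs))
    coeff_matrix = np.vstack(coeff_rows)
    cols = [f"{c}{n}" for n in range(1, config.H + 1) for c in "abcd"]
    coeff_df = pd.DataFrame(coeff_matrix, index=taxa, columns=cols)
    coeff_df.to_csv(out / "coefficients.csv")

    # ---- stage 3: morphospace + theoretical grid ---------------------------
    stage("morphospace")
    space = morphospace.fit_shape_space(coeff_matrix)
    scores = pd.DataFrame(
        space.scores[:, :2], index=taxa, columns=["pc1", "pc2"]
    )
    scores.to_csv(out / "scores.csv")
    pd.DataFrame(
        {"explained_variance": space.explained_variance}
    ).to_csv(out / "explained_variance.csv", index=False)

    grid = morphospace.build_theoretical_grid(
        space,
        n_cols=config.n_cols,
        n_rows=config.n_rows,
        border_frac=config.border_frac,
        P=config.P,
    )
    occupation = morphospace.occupation_fraction(grid, space.scores[:, :2])

    # ---- stage 4: performance ---------------------------------------------
    stage("performance (incl. FEA)")
    records = score_grid(grid, config)
    for metric in ("AR", "r2hat", "median_vms"):
        _, bands = performance.performance_landscape(
            grid, {metric: records[metric].to_numpy()}, metric
        )
        records[f"band_{metric}"] = bands
    records.to_csv(out / "grid_landscapes.csv", index=False)

    # ---- stage 5: Pareto optimality ----------------------------------------
    stage("pareto")
    spec = pareto.ObjectiveSpec(
        names=tuple(config.pareto_metrics),
        directions=tuple(config.pareto_directions),
    )
    viable = records[records["viable"]].reset_index(drop=True)
    land = pareto.optimality_landscape(viable, spec)
    ratio_full = np.full(grid.n_cells, np.nan)
    ratio_full[land.cell_ids] = land.rank_ratio
    opt = viable[["cell_id", "pc1", "pc2"]].copy()
    opt["f"] = land.forward_rank
    opt["b"] = land.reverse_rank
    opt["ratio"] = land.rank_ratio
    opt["band"] = land.bands
    for pair in [("AR", "median_vms"), ("AR", "r2hat"), ("r2hat", "median_vms")]:
        sub = pareto.optimality_landscape(viable, spec, pairwise=pair)
        opt[f"ratio_{pair[0]}_{pair[1]}"] = sub.rank_ratio
    opt.to_csv(out / "optimality.csv", index=False)

    # ---- stage 6: phylogenetic + regression analyses -----------------------
    stage("comparative")
    results_json = {
        "n_taxa": len(taxa),
        "n_cells": grid.n_cells,
        "n_viable": int(grid.viable.sum()),
        "occupation_fraction": occupation,
        "hull_area_fraction": morphospace.hull_area_fraction(
            grid, space.scores[:, :2]
        ),
        "explained_variance_pc1": float(space.explained_variance[0]),
        "explained_variance_pc2": float(space.explained_variance[1]),
    }
    if tree is not None:
        traits = coeff_df.loc[[t for t in taxa if t in set(phylo.tip_labels(tree))]]
        sig = phylo.kmult(
            tree, traits, n_iterations=config.kmult_iterations, seed=config.seed
        )
        results_json["kmult"] = {
            "K": sig.K, "p_value": sig.p_value, "iterations": sig.n_iterations
        }
        pms = phylo.phylomorphospace(tree, traits, space)
        pms.to_csv(out / "phylomorphospace.csv", index=False)
    if covariates is not None:
        data = scores.copy()
        cs = pd.Series(
            [outlines.centroid_size(r) for r in resampled], index=taxa
        )
        data["centroid_size"] = cs
        for col in ("mat", "mar"):
            if col in covariates:
                data[col] = covariates[col]
        if {"mat", "mar"}.issubset(data.columns):
            regression_table(data).to_csv(out / "regression_ols.csv", index=False)
            if tree is not None:
                regression_table(data, tree=tree).to_csv(
                    out / "regression_pgls.csv", index=False
                )

    # ---- artifacts ----------------------------------------------------------
    stage("artifacts")
    with open(out / "summary.json", "w") as fh:
        json.dump(results_json, fh, indent=2)
    cfg = asdict(config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    if config.make_plots:
        _plot_landscape(grid, records["AR"], out / "landscape_AR.png", "Aspect ratio")
        _plot_landscape(
            grid, records["r2hat"], out / "landscape_r2hat.png", "r2hat"
        )
        _plot_landscape(
            grid, records["median_vms"], out / "landscape_vms.png",
            "Median von Mises stress",
        )
        _plot_landscape(
            grid, ratio_full, out / "landscape_optimality.png",
            "Pareto rank ratio",
        )
    stage("done")
    return out
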