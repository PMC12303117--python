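"""Shared helpers for the numbered analysis drivers.

The study dataset is synthetic and fully determined by the config
recorded in ``results/data/dataset.json``; outlines are regenerated on
demand rather than stored, so every driver is reproducible from the
seed alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"
FLOAT_FMT = "%.6g"


def save_dataset_config(cfg) -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    with open(DATA / "dataset.json", "w") as fh:
        json.dump(
            {
                "n_taxa": cfg.n_taxa,
                "seed": cfg.seed,
                "bm_rate": cfg.bm_rate,
                "noise_sd": cfg.noise_sd,
                "latent_sd": list(cfg.latent_sd),
                "covariate_effects": cfg.covariate_effects,
            },
            fh,
            indent=2,
        )


def load_dataset():
    """Regenerate the study outlines + covariates; read the stored tree."""
    from wingmorph.phylo import read_newick
    from wingmorph.synth import SimulationConfig, gen_wing_set

    with open(DATA / "dataset.json") as fh:
        meta = json.load(fh)
    cfg = SimulationConfig(
        n_taxa=meta["n_taxa"],
        seed=meta["seed"],
        bm_rate=meta["bm_rate"],
        noise_sd=meta["noise_sd"],
        latent_sd=tuple(meta["latent_sd"]),
        covariate_effects=meta["covariate_effects"],
    )
    outlines, truth = gen_wing_set(cfg)
    tree = read_newick(DATA / "tree.nwk")
    return outlines, truth, tree, cfg


def quantified_shapes(P: int = 150, H: int = 9):
    """Standardized 150-point outlines and normalized coefficient matrix."""
    from wingmorph.efa import coeffs_to_vector, efa_forward, efa_normalize
    from wingmorph.outlines import orient_standard, resample_equal_arclength

    outlines, truth, tree, cfg = load_dataset()
    std = [resample_equal_arclength(orient_standard(o), P) for o in outlines]
    X = np.vstack(
        [coeffs_to_vector(efa_normalize(efa_forward(o, H))) for o in std]
    )
    return std, X, truth, tree, cfg
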