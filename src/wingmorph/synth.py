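"""Synthetic wing outlines, trees, Brownian traits and covariates.

The generator provides ground-truthed inputs for every downstream stage.
A wing planform is built from two smooth parametric edges sharing a
rounded base and tip: at spanwise fraction s in [0, 1] the half-width is

    h(s) = 0.5 * span * [(1 - s) * base_width_frac + s * tip_width_frac]
           * sin(pi * s) ** tip_roundness,

so the envelope closes smoothly at both ends (tip_roundness < 1 gives
elliptic-like rounded caps), and a camber bump m(s) = camber_asym * span
* s * (1 - s) skews the leading/trailing edges.  Shapes built this way
are simple (non-self-intersecting) by construction for parameters within
the documented bounds.

Two latent axes drive population-level variation, mirroring the wing
features the downstream PCA is expected to recover: ``breadth`` (overall
width relative to span) and ``tipness`` (apical-tip size relative to the
humeral base).  Covariates are linear in the latents plus Gaussian
noise, with configurable slopes, and a lognormal size factor scales each
outline so centroid size varies realistically.

A single integer seed controls all draws in a simulation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from wingmorph.outlines import as_outline

__all__ = [
    "WingParams",
    "SimulationConfig",
    "gen_wing_outline",
    "wing_from_latents",
    "gen_wing_set",
    "gen_tree",
    "simulate_bm",
]

_BOUNDS = {
    "base_width_frac": (0.02, 0.95),
    "tip_width_frac": (0.02, 0.95),
    "tip_roundness": (0.2, 1.5),
    "camber_asym": (-0.5, 0.5),
}


@dataclass(frozen=True)
class WingParams:
    """Geometric parameters of one synthetic wing planform."""

    span: float = 1.0
    base_width_frac: float = 0.35
    tip_width_frac: float = 0.35
    tip_roundness: float = 0.6
    camber_asym: float = 0.1

    def __post_init__(self):
        if not np.isfinite(self.span) or self.span <= 0:
            raise ValueError("span must be finite and > 0")
        for name, (lo, hi) in _BOUNDS.items():
            val = getattr(self, name)
            if not np.isfinite(val) or not (lo <= val <= hi):
                raise ValueError(
                    f"{name}={val} outside documented bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic wing-set simulation."""

    n_taxa: int = 60
    seed: int = 0
    bm_rate: float = 1.0
    covariate_effects: dict = field(
        default_factory=lambda: {"mat": 0.3, "mar": 0.0, "log_size": 0.3}
    )
    noise_sd: float = 0.3
    latent_sd: tuple = (1.0, 0.5)  # breadth, tipness spread

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.bm_rate < 0:
            raise ValueError("bm_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_wing_outline(params: WingParams, n_points: int = 200, seed: int = 0) -> np.ndarray:
    """Closed, simple wing outline with span along +x and base at min x.

    Deterministic given seed (the generator itself is deterministic; seed
    is accepted for interface uniformity and reserved for future jitter).
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    m = n_points // 2
    s = np.linspace(0.0, 1.0, m + 1)
    width = (1.0 - s) * params.base_width_frac + s * params.tip_width_frac
    half = 0.5 * params.span * width * np.sin(np.pi * s) ** params.tip_roundness
    mid = params.camber_asym * params.span * s * (1.0 - s)
    x = s * params.span
    upper = np.column_stack([x, mid + half])
    lower = np.column_stack([x, mid - half])
    # traverse lower edge base->tip, upper edge tip->base: CCW closed curve
    outline = np.vstack([lower, upper[::-1][1:-1]])
    return as_outline(outline)


def wing_from_latents(breadth: float, tipness: float, span: float = 1.0,
                      camber_asym: float = 0.1) -> WingParams:
    """Map latent axes to wing parameters.

    ``breadth`` scales overall width; ``tipness`` shifts width from the
    humeral base to the apical tip at constant total.  Both maps are
    linear (clipped only at the documented parameter bounds) so the
    downstream PCA can recover the axes: the mean coefficient response
    to each latent is then itself near-linear.
    """
    b = 0.33 + 0.06 * breadth
    t = 0.12 * tipness
    lo, hi = _BOUNDS["base_width_frac"]
    return WingParams(
        span=span,
        base_width_frac=float(np.clip(b - t, lo, hi)),
        tip_width_frac=float(np.clip(b + t, lo, hi)),
        tip_roundness=0.6,
        camber_asym=camber_asym,
    )


def gen_wing_set(config: SimulationConfig, n_points: int = 200):
    """Generate outlines plus a ground-truth covariate table.

    Latents are independent normals (scales ``config.latent_sd``); each
    covariate named in ``covariate_effects`` is slope * latent_breadth +
    noise (slopes act on the first latent axis, except ``log_size`` which
    also scales the outline).  Returns (outlines, table) where the table
    holds taxon, latent_breadth, latent_tipness, size, every covariate,
    and the generating slopes are recoverable by regression on the
    latents.
    """
    rng = np.random.default_rng(config.seed)
    z1 = rng.normal(0.0, config.latent_sd[0], config.n_taxa)  # breadth
    z2 = rng.normal(0.0, config.latent_sd[1], config.n_taxa)  # tipness
    eff = config.covariate_effects
    log_size = eff.get("log_size", 0.0) * z1 + rng.normal(
        0.0, config.noise_sd, config.n_taxa
    )
    size = np.exp(log_size)
    table = pd.DataFrame(
        {
            "taxon": [f"t{i}" for i in range(config.n_taxa)],
            "latent_breadth": z1,
            "latent_tipness": z2,
            "size": size,
        }
    ).set_index("taxon")
    for name, slope in eff.items():
        if name == "log_size":
            continue
        table[name] = slope * z1 + rng.normal(0.0, config.noise_sd, config.n_taxa)

    outlines = []
    for i in range(config.n_taxa):
        params = wing_from_latents(z1[i], z2[i], span=size[i])
        outlines.append(gen_wing_outline(params, n_points=n_points, seed=config.seed))
    return outlines, table


def gen_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Rooted binary pure-birth (Yule) tree with n_tips extant tips."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.seed_node.edge.length = None  # no root edge
    # the simulation stops exactly at the birth creating the n-th tip, so
    # the newest pendant edges have length 0; advance the present by a
    # draw from the waiting time to the next birth (Exp(n * birth_rate))
    # to keep the tree ultrametric with strictly positive branches
    dt = rng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and (edge.length or 0.0) <= 0.0:
            raise RuntimeError("pure-birth simulation produced a non-positive branch")
    return tree


def simulate_bm(
    tree: dendropy.Tree, n_traits: int = 1, rate: float = 1.0, seed: int = 0,
    root_value: float = 0.0,
) -> pd.DataFrame:
    """Tip values of independent Brownian traits evolved along the tree.

    Tips are jointly normal with covariance rate * C (C the shared
    path-length matrix), independent across traits.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    from wingmorph.phylo import phylo_vcv, tip_labels

    labels = tip_labels(tree)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        Y = np.full((n, n_traits), root_value)
    else:
        C = phylo_vcv(tree, labels)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        Z = rng.standard_normal((n, n_traits))
        Y = root_value + np.sqrt(rate) * (L @ Z)
    return pd.DataFrame(
        Y, index=labels, columns=[f"trait{j}" for j in range(n_traits)]
    )
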