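import numpy as np
import pytest

from wingmorph.outlines import orient_standard, resample_equal_arclength
from wingmorph.synth import WingParams, gen_wing_outline


@pytest.fixture(scope="session")
def wing_outline():
    """One asymmetric synthetic wing, standardized and resampled to 150 pts."""
    params = WingParams(
        span=1.0,
        base_width_frac=0.3,
        tip_width_frac=0.45,
        tip_roundness=0.6,
        camber_asym=0.12,
    )
    raw = gen_wing_outline(params, n_points=200, seed=0)
    return resample_equal_arclength(orient_standard(raw), 150)


@pytest.fixture(scope="session")
def wing_population():
    """50 wings spanning both latent axes, as 150-point standardized outlines."""
    from wingmorph.synth import SimulationConfig, gen_wing_set

    cfg = SimulationConfig(n_taxa=50, seed=42, noise_sd=0.05)
    outlines, truth = gen_wing_set(cfg)
    std = [resample_equal_arclength(orient_standard(o), 150) for o in outlines]
    return std, truth


@pytest.fixture(scope="session")
def coefficient_matrix(wing_population):
    from wingmorph.efa import coeffs_to_vector, efa_forward, efa_normalize

    std, _ = wing_population
    return np.vstack(
        [coeffs_to_vector(efa_normalize(efa_forward(o, 9))) for o in std]
    )


@pytest.fixture(scope="session")
def shape_space(coefficient_matrix):
    from wingmorph.morphospace import fit_shape_space

    return fit_shape_space(coefficient_matrix)


@pytest.fixture(scope="session")
def small_tree():
    from wingmorph.synth import gen_tree

    return gen_tree(16, seed=3)


@pytest.fixture(scope="session")
def star_tree():
    import dendropy

    nwk = "(" + ",".join(f"t{i}:1.0" for i in range(10)) + ");"
    return dendropy.Tree.get(data=nwk, schema="newick")
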