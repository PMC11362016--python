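import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from thymoquant.synth import PhantomSpec, make_phantom, ExprSimSpec, make_expression


SMALL_PHANTOM_KW = dict(
    lobe_semi_axes=(60.0, 40.0, 40.0),
    voxel_spacing=(4.0, 1.0, 1.0),
    shape=(40, 112, 112),
    n_medulla_blobs=1,
    medulla_blob_radius=14.0,
    hd_fraction=0.5,
    hd_shell_thickness=10.0,
    boundary_clearance=8.0,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A fast, small aged-type phantom with one coated medullary blob."""
    spec = PhantomSpec(seed=7, **SMALL_PHANTOM_KW)
    stack, truth = make_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def expr_adata():
    """Default synthetic expression matrix with truth labels."""
    return make_expression(ExprSimSpec(seed=11))


@pytest.fixture(scope="session")
def normalized_expr(expr_adata):
    from thymoquant.expr import normalize_log1p

    return normalize_log1p(expr_adata.X)
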