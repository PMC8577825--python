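import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210702)


@pytest.fixture(scope="session")
def contact_scene_and_stack():
    """One rendered portal-tract field at study-like contact conditions."""
    from portalquant.synthetic import RenderConfig, TissueParams, generate_tissue_scene, render_tissue

    params = TissueParams(n_dc=50, n_msc=15, contact_fraction=0.92, field_um=300)
    scene = generate_tissue_scene(params, seed=11)
    stack = render_tissue(scene, RenderConfig.for_tissue(scene, seed=11))
    return scene, stack


@pytest.fixture(scope="session")
def organoid_scene_and_stack():
    from portalquant.synthetic import (
        OrganoidParams,
        RenderConfig,
        generate_organoid_scene,
        render_organoid,
    )

    scene = generate_organoid_scene(
        OrganoidParams(gfp_area_fraction=0.25, n_tomato_clusters=3), seed=5
    )
    stack = render_organoid(scene, RenderConfig.for_organoid(scene, seed=5))
    return scene, stack
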