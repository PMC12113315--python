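import pytest

from strutcast.materials import Blend, Material


@pytest.fixture(scope="session")
def pcl() -> Material:
    return Material(
        name="PCL",
        density_ref=1145.0,
        T_ref_density=25.0,
        cte=165e-6,
        eta_ref=2211.35,
        T_ref_visc=120.0,
        surface_tension=0.040,
        contact_angle=75.0,
    )


@pytest.fixture(scope="session")
def dmso2() -> Material:
    return Material(
        name="DMSO2",
        density_ref=1450.0,
        T_ref_density=25.0,
        cte=88e-6,
        eta_ref=0.00114,
        T_ref_visc=120.0,
        surface_tension=0.060,
        contact_angle=40.0,
    )


@pytest.fixture(scope="session")
def blend_series(pcl, dmso2) -> dict[str, Blend]:
    """PCL with 0/10/20/30 wt% DMSO2."""
    return {
        "pcl": Blend.of((pcl, 1.0)),
        "pcl_d10": Blend.of((pcl, 0.9), (dmso2, 0.1)),
        "pcl_d20": Blend.of((pcl, 0.8), (dmso2, 0.2)),
        "pcl_d30": Blend.of((pcl, 0.7), (dmso2, 0.3)),
    }
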