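import numpy as np
import pytest

import lumenflow as lf

#: pixel size used by most toy fixtures (µm)
PX = 1.5625


@pytest.fixture(scope="session")
def straight_channel():
    """100 µm channel along columns, 64 px wide in a 128x256 image."""
    return lf.generate_toy_geometry(
        lf.ToyGeometrySpec("straight_channel", width_um=100.0, image_shape_px=(128, 256))
    )


@pytest.fixture(scope="session")
def y_branch():
    return lf.generate_toy_geometry(
        lf.ToyGeometrySpec("y_branch", width_um=60.0, image_shape_px=(192, 256))
    )


@pytest.fixture(scope="session")
def bridge_lattice():
    return lf.generate_toy_geometry(
        lf.ToyGeometrySpec("bridge_lattice", width_um=60.0, image_shape_px=(192, 256))
    )


@pytest.fixture(scope="session")
def lattice():
    return lf.generate_toy_geometry(
        lf.ToyGeometrySpec("lattice", width_um=50.0, image_shape_px=(256, 320))
    )


@pytest.fixture(scope="session")
def cols_flow():
    """Flow configuration matching the toy orientation (inlet = left border)."""
    return lf.FlowConfig(flow_axis="cols")


@pytest.fixture(scope="session")
def straight_solution(straight_channel, cols_flow):
    domain = lf.build_domain(straight_channel, cols_flow)
    field = lf.solve_flow(domain, cols_flow)
    return domain, field


@pytest.fixture(scope="session")
def y_branch_frame(y_branch, cols_flow):
    return lf.analyze_frame(y_branch, flow_config=cols_flow)


@pytest.fixture(scope="session")
def bridge_frame(bridge_lattice, cols_flow):
    return lf.analyze_frame(bridge_lattice, flow_config=cols_flow)


@pytest.fixture(scope="session")
def lattice_frame(lattice, cols_flow):
    return lf.analyze_frame(lattice, flow_config=cols_flow)


def small_timelapse_config(seed: int, **kw) -> "lf.TimelapseConfig":
    """Scaled-down study conditions: 256x384 px chamber, 4 frames per stage."""
    kw.setdefault("pixel_size_um", 7.8125)
    return lf.TimelapseConfig(seed=seed, **kw)
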