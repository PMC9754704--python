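import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nupdi import SimCellConfig, render_frame

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_nucleus():
    """Rendered noiseless nucleus: shell 200, interior 50, no background.

    radius 16 px, shell 3 px, histone channel filling the whole nucleus
    so the histone mask traces the nuclear boundary.  True DI = 0.25.
    """
    cfg = SimCellConfig(
        "cell0", (32.0, 32.0), 16.0, 3.0,
        c_ne=[200.0], c_np=[50.0], background=0.0,
        histone_radius_frac=1.0,
    )
    frame = render_frame(cfg, 0, (64, 64))
    return cfg, frame


def aligned_masks(shape=(64, 64), center=(32.0, 32.0), radius=16.0, shell=3.0):
    """Compartment masks aligned to the rendered shell by construction:

    nucleoplasm = fully-interior pixels, envelope = fully-shell pixels,
    keeping the anti-aliased edge ramps out of both compartments.
    """
    from nupdi import CompartmentMasks

    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    inner = radius - shell
    nucleoplasm = r <= inner - 1.0
    envelope = (r >= inner + 0.5) & (r <= radius - 0.5)
    nuclear = r <= radius - 0.5
    return CompartmentMasks(nuclear, nucleoplasm, envelope,
                            erosion_radius=0, dilation_radius=0)
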