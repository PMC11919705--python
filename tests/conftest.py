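import numpy as np
import pytest

from catfish.imagequant import ROI
from catfish.synth import ActivityModel, render_zstack, sample_nuclei


def square_polygon(shape, margin=8):
    ny, nx = shape
    return [
        (margin, margin),
        (nx - margin, margin),
        (nx - margin, ny - margin),
        (margin, ny - margin),
    ]


@pytest.fixture(scope="session")
def small_field():
    """One rendered 7-layer field with ground truth, shared across tests."""
    shape = (256, 256)
    poly = square_polygon(shape)
    model = ActivityModel(p_first=0.3, p_second=0.25, rho=0.0)
    density = 30 / ((shape[0] - 16) ** 2)  # ~30 nuclei per layer
    nuclei = sample_nuclei(poly, density, model, n_layers=7, rng_seed=11)
    stack = render_zstack(nuclei, shape, rng_seed=11, n_layers=7)
    roi = ROI(structure="VTA", polygon=np.asarray(poly, float))
    return {"shape": shape, "poly": poly, "nuclei": nuclei, "stack": stack,
            "roi": roi, "model": model}
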