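import numpy as np
import pytest
from skimage import transform

import flowmorph as fm


@pytest.fixture(scope="session")
def flow_x() -> fm.FlowField:
    return fm.FlowField((1.0, 0.0))


@pytest.fixture(scope="session")
def aligned_monolayer() -> fm.SyntheticScene:
    """200-cell monolayer, strongly flow-aligned, eccentricity 0.8."""
    cfg = fm.SceneConfig(
        n_cells=200, width=1024, height=1024, seed=0,
        orientation_law=fm.AngularLaw("von_mises", 0.0, 50.0), ecc_target=0.8,
    )
    return fm.make_monolayer(cfg)


@pytest.fixture(scope="session")
def small_monolayer() -> fm.SyntheticScene:
    cfg = fm.SceneConfig(n_cells=50, seed=1)
    return fm.make_monolayer(cfg)


def label_image_from_cells(cells: np.ndarray, pixel_size: float = 1.0) -> fm.LabelImage:
    """Wrap a cell label raster, flagging labels on the image border."""
    edge = np.unique(np.concatenate([cells[0], cells[-1], cells[:, 0], cells[:, -1]]))
    return fm.LabelImage(
        cells.astype(np.int32), pixel_size, frozenset(int(v) for v in edge if v > 0)
    )


def rotate_label_image(lab: np.ndarray, deg: float) -> np.ndarray:
    """Sub-pixel rotation of a label image.

    Each label's mask is rotated with bilinear interpolation and
    re-thresholded at 0.5, so straight boundaries stay straight instead of
    acquiring a nearest-neighbour staircase; contested pixels go to the
    label with the larger interpolated weight.
    """
    n = int(lab.max())
    shape = transform.rotate(np.zeros(lab.shape), deg, resize=True).shape
    out = np.zeros(shape, np.int32)
    weight = np.zeros(shape)
    for k in range(1, n + 1):
        w = transform.rotate((lab == k).astype(float), deg, resize=True, order=1)
        sel = (w > 0.5) & (w > weight)
        out[sel] = k
        weight[sel] = w[sel]
    return out
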