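import numpy as np
import pytest

from ihcquant.stains import hdab_vectors, to_inverted_gray, unmix
from ihcquant.synthetic import make_puncta_scene, make_snr_scene, make_wt_ko_pair, render_scene


@pytest.fixture(scope="session")
def hdab_matrix():
    return hdab_vectors().matrix


@pytest.fixture(scope="session")
def snr_pair():
    """Rendered wild-type / knockout pair with moderate specific DAB."""
    spec = make_snr_scene(0.5, seed=11, size_px=128)
    wt, ko, gt = make_wt_ko_pair(spec)
    return wt, ko, gt


@pytest.fixture(scope="session")
def puncta_scene():
    """Rendered scene with planted puncta, decoys and its DAB gray image."""
    spec = make_puncta_scene(puncta_per_cell=(0, 0, 1, 2, 5),
                             decoys_per_cell=(1, 1, 1, 1, 1), seed=21)
    img, gt = render_scene(spec)
    _, dab, _ = unmix(img)
    return spec, gt, to_inverted_gray(dab)


def render_od_pairs(od_pairs: np.ndarray) -> np.ndarray:
    """Render an (n, 2) array of (hema, dab) ODs as a 1 x n RGB image."""
    M = hdab_vectors().matrix
    od_rgb = od_pairs[:, 0:1] * M[:, 0] + od_pairs[:, 1:2] * M[:, 1]
    img = np.clip(np.rint(255.0 * 10.0 ** -od_rgb), 0, 255)
    return img.astype(np.uint8).reshape(1, -1, 3)
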