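import warnings

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse

from chromfract import NucleusSurface


@pytest.fixture(autouse=True)
def _quiet_support_warnings():
    """Small test surfaces routinely trip the e_max support warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="nucleus bounding box")
        warnings.filterwarnings("ignore", message="case .* nuclei")
        yield


def make_surface(gray, mask=None, pixel_size_um=1.0):
    gray = np.asarray(gray, dtype=np.uint8)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    return NucleusSurface(gray=gray, mask=mask, pixel_size_um=pixel_size_um)


def disk_mask(radius, pad=3):
    n = 2 * radius + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    rr, cc = disk((n // 2, n // 2), radius)
    m[rr, cc] = True
    return m


def ellipse_mask(a, b, pad=3):
    n = 2 * max(a, b) + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    rr, cc = ellipse(n // 2, n // 2, a, b, shape=(n, n))
    m[rr, cc] = True
    return m


def random_blob_mask(rng, n=32):
    """A random connected single-component mask (largest blob)."""
    from scipy import ndimage

    raw = rng.random((n, n)) < 0.75
    lab, k = ndimage.label(raw, structure=np.ones((3, 3)))
    sizes = ndimage.sum(raw, lab, range(1, k + 1))
    return lab == (1 + int(np.argmax(sizes)))


def exponential_cohort(n, b, seed, censor_rate=0.01, baseline=0.03,
                       covariate="x", binary=False, extra_noise=False):
    """Tabular proportional-hazards cohort with a single known effect.

    Continuous times (no ties); optional independent binary noise column.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float) if binary else rng.normal(0, 1, n)
    t = rng.exponential(1.0 / (baseline * np.exp(b * x)))
    c = rng.exponential(1.0 / censor_rate, n)
    df = pd.DataFrame(
        {
            "time_months": np.maximum(np.minimum(t, c), 1e-3),
            "event": t <= c,
            covariate: x,
        }
    )
    if extra_noise:
        df["noise"] = rng.integers(0, 2, n).astype(float)
    return df
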