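"""Classical comparison detectors: Sobel, Prewitt, Roberts, LoG, Canny.

These are the established gradient / second-derivative operators the fuzzy
detector is benchmarked against.  The filter kernels come from
scikit-image and scipy.ndimage; this module adds the thresholding policies,
the shared bilevel output contract (boolean map, 1-pixel border never
flagged) and a small registry used by the evaluation harness.

Thresholds the comparison protocol leaves open default to automatic
choices: Otsu's threshold on the gradient magnitude for the first-derivative
operators, a mean-|response| gate for LoG zero crossings, and absolute
hysteresis levels on the unit-scaled gradient for Canny.  All of them are
parameters.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import feature, filters

__all__ = [
    "gradient_detector",
    "log_detector",
    "canny_detector",
    "get_detector",
    "BASELINE_NAMES",
]

_GRADIENT_FILTERS: dict[str, Callable] = {
    "sobel": filters.sobel,
    "prewitt": filters.prewitt,
    "roberts": filters.roberts,
}

BASELINE_NAMES = ("sobel", "prewitt", "roberts", "log", "canny")


def _as_float(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {arr.shape}")
    return arr / 255.0


def _clear_border(edges: np.ndarray) -> np.ndarray:
    edges[0, :] = edges[-1, :] = False
    edges[:, 0] = edges[:, -1] = False
    return edges


def gradient_detector(image, kernel_name: str, threshold: float | None = None) -> np.ndarray:
    """First-derivative edge map via Sobel, Prewitt or Roberts kernels.

    ``threshold`` is a fraction of the maximum gradient magnitude; ``None``
    selects Otsu's automatic threshold on the magnitude image.
    """
    if kernel_name not in _GRADIENT_FILTERS:
        raise ValueError(
            f"unknown kernel {kernel_name!r}; choose from {sorted(_GRADIENT_FILTERS)}"
        )
    arr = _as_float(image)
    mag = _GRADIENT_FILTERS[kernel_name](arr)
    if mag.max() == mag.min():
        return np.zeros(arr.shape, dtype=bool)
    if threshold is None:
        thr = filters.threshold_otsu(mag)
    else:
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("fixed threshold must be a fraction in [0, 1]")
        thr = threshold * mag.max()
    return _clear_border(mag > thr)


def log_detector(image, sigma: float = 2.0, gate_frac: float = 0.75) -> np.ndarray:
    """Laplacian-of-Gaussian zero crossings with a response-magnitude gate.

    A pixel is flagged where its 3x3 neighbourhood straddles zero and the
    local response swing exceeds ``gate_frac`` times the mean absolute LoG
    response (a zero gate on a flat image flags nothing).
    """
    arr = _as_float(image)
    log = ndimage.gaussian_laplace(arr, sigma=sigma)
    footprint = np.ones((3, 3))
    local_max = ndimage.maximum_filter(log, footprint=footprint)
    local_min = ndimage.minimum_filter(log, footprint=footprint)
    crossing = (local_min < 0.0) & (local_max > 0.0)
    gate = gate_frac * np.mean(np.abs(log))
    return _clear_border(crossing & (local_max - local_min > gate))


def canny_detector(
    image, sigma: float = 1.0, low_frac: float = 0.1, high_frac: float = 0.2
) -> np.ndarray:
    """Canny edge map: Gaussian gradient, non-maximum suppression, hysteresis.

    ``low_frac``/``high_frac`` are the hysteresis thresholds on the gradient
    magnitude of the unit-scaled image.
    """
    if not (0.0 <= low_frac <= high_frac <= 1.0):
        raise ValueError("hysteresis fractions must satisfy 0 <= low <= high <= 1")
    arr = _as_float(image)
    edges = feature.canny(
        arr, sigma=sigma, low_threshold=low_frac, high_threshold=high_frac
    )
    return _clear_border(edges.copy())


def get_detector(name: str, **params) -> Callable[[np.ndarray], np.ndarray]:
    """Detector callable (image -> boolean edge map) by registry name."""
    name = name.lower()
    if name in _GRADIENT_FILTERS:
        return lambda img: gradient_detector(img, name, **params)
    if name == "log":
        return lambda img: log_detector(img, **params)
    if name == "canny":
        return lambda img: canny_detector(img, **params)
    raise ValueError(f"unknown baseline detector {name!r}; choose from {BASELINE_NAMES}")
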