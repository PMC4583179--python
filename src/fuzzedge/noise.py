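"""Salt-and-pepper noise, MSE/PSNR metrics, and PSNR-targeted calibration.

Noise severity in the evaluation protocol is expressed as a peak
signal-to-noise ratio in dB rather than a corruption density, so the module
provides a bisection search that finds the density ``p`` at which the
realized PSNR of the corrupted image hits a requested target.  The search
reuses one seeded random field for every probe: the set of corrupted pixels
at density ``p1 < p2`` is then nested, making the realized MSE monotone in
``p`` and the bisection well posed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["NoiseReport", "add_salt_pepper", "mse", "psnr", "calibrate_density"]

#: Peak intensity of an 8-bit unsigned image.
PEAK = 255.0


@dataclass
class NoiseReport:
    """Realized corruption of one noisy image: density, seed, MSE, PSNR."""

    density: float
    seed: int
    mse: float
    psnr_db: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def add_salt_pepper(image, p: float, seed: int | None = None) -> np.ndarray:
    """Corrupt each pixel independently with probability ``p``.

    A corrupted pixel is set to 0 or 255 with equal probability.  The same
    ``seed`` always corrupts the same pixels, and the corrupted set at a
    lower density is a subset of the set at a higher density.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"density must lie in [0, 1], got {p}")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {arr.shape}")
    rng = np.random.default_rng(seed)
    u = rng.random(arr.shape)
    salt = rng.random(arr.shape) < 0.5
    corrupted = u < p
    out = arr.copy()
    out[corrupted & salt] = 255
    out[corrupted & ~salt] = 0
    return out


def mse(a, b) -> float:
    """Mean squared intensity difference between two equal-shaped images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    return float(np.mean(diff * diff))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio ``10 log10(255^2 / MSE)`` in dB.

    Raises if the images are identical (MSE = 0), where the ratio is
    undefined.
    """
    err = mse(a, b)
    if err == 0.0:
        raise ValueError("PSNR is undefined for identical images (MSE = 0)")
    return float(10.0 * np.log10(PEAK * PEAK / err))


def calibrate_density(
    image,
    target_db: float,
    tol_db: float = 0.25,
    seed: int | None = None,
    max_iter: int = 80,
) -> tuple[float, NoiseReport]:
    """Bisection on the corruption density until the realized PSNR hits target.

    Returns the density and the noise report of the accepted noisy image;
    ``add_salt_pepper(image, p, seed)`` regenerates that image exactly.
    With ``tol_db = inf`` the first probe (p = 0.5) is accepted as-is.
    """
    arr = np.asarray(image)
    if not np.isfinite(target_db) or target_db <= 0:
        raise ValueError(f"target PSNR must be finite and positive, got {target_db} dB")

    def realized(p: float) -> float:
        noisy = add_salt_pepper(arr, p, seed)
        err = mse(arr, noisy)
        return np.inf if err == 0.0 else 10.0 * np.log10(PEAK * PEAK / err)

    floor_db = realized(1.0)
    if target_db < floor_db:
        raise ValueError(
            f"target {target_db} dB below the full-corruption floor "
            f"{floor_db:.3f} dB for this image — not bracketable"
        )

    lo, hi = 0.0, 1.0  # PSNR(lo) = +inf >= target >= PSNR(hi)
    for _ in range(max_iter):
        p = 0.5 * (lo + hi)
        db = realized(p)
        if abs(db - target_db) <= tol_db:
            noisy = add_salt_pepper(arr, p, seed)
            report = NoiseReport(
                density=p,
                seed=-1 if seed is None else int(seed),
                mse=mse(arr, noisy),
                psnr_db=float(db),
            )
            return p, report
        if db > target_db:
            lo = p
        else:
            hi = p
    raise RuntimeError(
        f"calibration did not reach {target_db} +/- {tol_db} dB in {max_iter} "
        f"bisection steps (image too small for that granularity?)"
    )
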