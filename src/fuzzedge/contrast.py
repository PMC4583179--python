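"""Fuzzy contrast intensification for smooth, low-contrast images.

Each pixel is mapped independently through a three-rule Mamdani system —
Darker input drives the Darkest output, Grey drives Grey, Brighter drives
Brightest — followed by centroid defuzzification.  The induced intensity
transfer function is a monotone S-curve that pushes dark pixels darker and
bright pixels brighter while leaving mid-grey fixed, which amplifies weak
steps so the edge detector's ``Higher`` set can saturate on them.

The default membership functions are symmetric about mid-grey (127.5): the
Darker/Brighter supports cover the two ends of the intensity axis and
overlap the narrow Grey triangle around the midpoint, giving the transfer
function a slope well above 1 across the central band (roughly grey levels
90-165) and a compressive plateau at the extremes.  A 35-level step at
110/145 is stretched to roughly 60 levels, enough for the edge rules to
clear the binarization threshold.

Because the mapping is a per-level look-up table, contrast adjustment of a
uniform image is uniform and the whole stage costs one table build plus one
fancy-index per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fuzzy_core import (
    FuzzyRule,
    FuzzySet,
    GaussianMF,
    OutputUniverse,
    TrapezoidalMF,
    defuzzify_batch,
    mf_center,
)

__all__ = [
    "ContrastConfig",
    "default_contrast_input_sets",
    "default_contrast_output_sets",
    "default_contrast_rules",
    "transfer_function",
    "transfer_lut",
    "adjust_contrast",
]


def default_contrast_input_sets() -> dict[str, FuzzySet]:
    return {
        "Darker": FuzzySet("Darker", TrapezoidalMF(0, 0, 60, 140)),
        "Grey": FuzzySet("Grey", TrapezoidalMF(90, 125, 130, 165)),
        "Brighter": FuzzySet("Brighter", TrapezoidalMF(115, 195, 255, 255)),
    }


def default_contrast_output_sets() -> dict[str, FuzzySet]:
    return {
        "Darkest": FuzzySet("Darkest", GaussianMF(m=5, d=15)),
        "Grey": FuzzySet("Grey", GaussianMF(m=127.5, d=15)),
        "Brightest": FuzzySet("Brightest", GaussianMF(m=250, d=15)),
    }


def default_contrast_rules() -> tuple[FuzzyRule, ...]:
    return (
        FuzzyRule({1: "Darker"}, "Darkest", n_inputs=1),
        FuzzyRule({1: "Grey"}, "Grey", n_inputs=1),
        FuzzyRule({1: "Brighter"}, "Brightest", n_inputs=1),
    )


@dataclass
class ContrastConfig:
    """Fuzzy sets, rules and universe resolution of the contrast stage."""

    input_sets: dict[str, FuzzySet] = field(default_factory=default_contrast_input_sets)
    output_sets: dict[str, FuzzySet] = field(default_factory=default_contrast_output_sets)
    rules: tuple[FuzzyRule, ...] = field(default_factory=default_contrast_rules)
    universe: OutputUniverse = field(default_factory=OutputUniverse)

    def __post_init__(self) -> None:
        for rule in self.rules:
            for _, label in rule.antecedents:
                if label not in self.input_sets:
                    raise ValueError(f"rule references unknown input set {label!r}")
            if rule.consequent not in self.output_sets:
                raise ValueError(f"rule references unknown output set {rule.consequent!r}")
        centers = [
            mf_center(self.output_sets[r.consequent].mf) for r in self.rules
        ]
        if sorted(set(centers)) != sorted(centers) or len(set(centers)) != len(centers):
            raise ValueError("output-set centres must be distinct")

    @property
    def grey_center(self) -> float:
        # fallback for a level no input set covers (impossible with defaults)
        mids = [mf_center(s.mf) for s in self.output_sets.values()]
        return float(np.median(mids))


def transfer_function(config: ContrastConfig | None = None) -> np.ndarray:
    """Unrounded crisp output for every integer grey level 0..255."""
    config = config or ContrastConfig()
    levels = np.arange(256, dtype=np.float64)
    agg: dict[str, np.ndarray] = {}
    for rule in config.rules:
        s = None
        for j, label in rule.antecedents:
            mu = np.asarray(config.input_sets[label](levels), dtype=np.float64)
            s = mu if s is None else np.minimum(s, mu)
        if rule.consequent in agg:
            agg[rule.consequent] = np.maximum(agg[rule.consequent], s)
        else:
            agg[rule.consequent] = s
    return defuzzify_batch(
        agg, config.output_sets, config.universe, fallback=config.grey_center
    )


def transfer_lut(config: ContrastConfig | None = None) -> np.ndarray:
    """Integer look-up table (nearest grey level, ties to even)."""
    t = transfer_function(config)
    return np.clip(np.rint(t), 0, 255).astype(np.uint8)


def adjust_contrast(image, config: ContrastConfig | None = None) -> np.ndarray:
    """Apply the fuzzy intensity transfer to an 8-bit grey image."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("contrast adjustment expects integer grey levels")
        arr = np.rint(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("grey levels must lie in [0, 255]")
    lut = transfer_lut(config)
    return lut[arr.astype(np.intp)]
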