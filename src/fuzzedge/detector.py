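"""Fuzzy-rule edge detection with a 3x3 difference mask.

For every interior pixel ``P`` the eight neighbourhood differences
``dP_j = |P_j - P|`` are computed, each difference is fuzzified into
``Lower`` / ``Higher`` sets, a 12-rule Mamdani knowledge base produces an
``Edge`` activation, and centroid defuzzification yields a crisp edge score
on the grey-level scale.  Pixels whose score reaches the binarization
threshold are flagged in the output edge map.

The rule base pairs two ``Higher`` differences on one side of the
neighbourhood with a ``Lower`` difference on the opposite side, so a genuine
intensity step activates strongly while an isolated impulse — whose *every*
difference is large — activates no rule at all.  That asymmetry is the
mechanism of the detector's salt-and-pepper robustness.

Because the knowledge base contains only Edge-consequent rules, the
``NonEdge`` set receives an implicit-else strength ``1 - max(rule
strengths)``; the aggregate output profile is therefore never empty and the
edge score is a continuous function of the neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

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
    "NEIGHBOR_OFFSETS",
    "DEFAULT_NEIGHBOR_ORDER",
    "DetectorConfig",
    "default_input_sets",
    "default_output_sets",
    "default_rules",
    "extract_deltas",
    "edge_score",
    "score_map",
    "detect_edges",
]

#: Compass names of the eight 3x3 neighbours and their (row, col) offsets.
NEIGHBOR_OFFSETS: dict[str, tuple[int, int]] = {
    "NW": (-1, -1), "N": (-1, 0), "NE": (-1, 1),
    "W": (0, -1), "E": (0, 1),
    "SW": (1, -1), "S": (1, 0), "SE": (1, 1),
}

#: Row-major neighbour convention: P1..P8 = NW, N, NE, W, E, SW, S, SE.
DEFAULT_NEIGHBOR_ORDER: tuple[str, ...] = ("NW", "N", "NE", "W", "E", "SW", "S", "SE")


def default_input_sets() -> dict[str, FuzzySet]:
    """Lower/Higher trapezoids shared by all eight difference inputs."""
    return {
        "Lower": FuzzySet("Lower", TrapezoidalMF(0, 0, 25, 75)),
        "Higher": FuzzySet("Higher", TrapezoidalMF(25, 75, 255, 255)),
    }


def default_output_sets() -> dict[str, FuzzySet]:
    """NonEdge/Edge output Gaussians centred at grey levels 10 and 245."""
    return {
        "NonEdge": FuzzySet("NonEdge", GaussianMF(m=10, d=3.5)),
        "Edge": FuzzySet("Edge", GaussianMF(m=245, d=3.5)),
    }


# Each row: two Higher differences on one flank, one Lower on the opposite
# flank.  Rows 1-4 oppose the SE neighbour, 5-8 the S, 9-12 the E.
_RULE_TABLE: tuple[tuple[dict[int, str], str], ...] = (
    ({1: "Higher", 2: "Higher", 8: "Lower"}, "Edge"),
    ({1: "Higher", 4: "Higher", 8: "Lower"}, "Edge"),
    ({2: "Higher", 3: "Higher", 8: "Lower"}, "Edge"),
    ({4: "Higher", 6: "Higher", 8: "Lower"}, "Edge"),
    ({1: "Higher", 2: "Higher", 7: "Lower"}, "Edge"),
    ({1: "Higher", 4: "Higher", 7: "Lower"}, "Edge"),
    ({2: "Higher", 3: "Higher", 7: "Lower"}, "Edge"),
    ({4: "Higher", 6: "Higher", 7: "Lower"}, "Edge"),
    ({1: "Higher", 2: "Higher", 5: "Lower"}, "Edge"),
    ({1: "Higher", 4: "Higher", 5: "Lower"}, "Edge"),
    ({2: "Higher", 3: "Higher", 5: "Lower"}, "Edge"),
    ({4: "Higher", 6: "Higher", 5: "Lower"}, "Edge"),
)


def default_rules() -> tuple[FuzzyRule, ...]:
    """The 12-rule edge knowledge base (Edge consequents only)."""
    return tuple(FuzzyRule(ants, cons) for ants, cons in _RULE_TABLE)


@dataclass
class DetectorConfig:
    """Everything that parameterizes the fuzzy edge detector.

    ``threshold`` must lie strictly between the two output-set centres; the
    default 127.5 is the midpoint of the NonEdge (10) and Edge (245)
    centres.  ``neighbor_order`` names which compass neighbour each input
    index P1..P8 refers to.
    """

    input_sets: dict[str, FuzzySet] = field(default_factory=default_input_sets)
    output_sets: dict[str, FuzzySet] = field(default_factory=default_output_sets)
    rules: tuple[FuzzyRule, ...] = field(default_factory=default_rules)
    universe: OutputUniverse = field(default_factory=OutputUniverse)
    threshold: float = 127.5
    neighbor_order: tuple[str, ...] = DEFAULT_NEIGHBOR_ORDER

    def __post_init__(self) -> None:
        centers = sorted(mf_center(s.mf) for s in self.output_sets.values())
        if not (centers[0] < self.threshold < centers[-1]):
            raise ValueError(
                f"threshold {self.threshold} must lie strictly between the "
                f"output centres {centers[0]} and {centers[-1]}"
            )
        if len(self.neighbor_order) != 8 or set(self.neighbor_order) != set(NEIGHBOR_OFFSETS):
            raise ValueError("neighbor_order must be a permutation of the 8 compass names")
        for rule in self.rules:
            for _, label in rule.antecedents:
                if label not in self.input_sets:
                    raise ValueError(f"rule references unknown input set {label!r}")
            if rule.consequent not in self.output_sets:
                raise ValueError(f"rule references unknown output set {rule.consequent!r}")

    @property
    def nonedge_center(self) -> float:
        return mf_center(self.output_sets["NonEdge"].mf)


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image {arr.shape} is smaller than the 3x3 mask")
    a = arr.astype(np.float64)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("grey levels must lie in [0, 255]")
    return a


def extract_deltas(
    image, row: int, col: int, neighbor_order: Sequence[str] = DEFAULT_NEIGHBOR_ORDER
) -> np.ndarray:
    """Absolute neighbour-centre differences dP_1..dP_8 at one interior pixel."""
    arr = _validate_image(image)
    m, n = arr.shape
    if not (1 <= row <= m - 2 and 1 <= col <= n - 2):
        raise ValueError(f"({row}, {col}) is not an interior pixel of a {m}x{n} image")
    center = arr[row, col]
    deltas = np.empty(8, dtype=np.float64)
    for j, name in enumerate(neighbor_order):
        dr, dc = NEIGHBOR_OFFSETS[name]
        deltas[j] = abs(arr[row + dr, col + dc] - center)
    return deltas


def _edge_aggregates(
    delta_arrays: Sequence[np.ndarray], config: DetectorConfig
) -> dict[str, np.ndarray]:
    """Per-pixel aggregate strengths for every consequent label.

    ``delta_arrays`` holds the eight difference planes (index j-1 = input
    P_j); scalars are accepted and broadcast.  NonEdge additionally receives
    the implicit-else strength ``1 - max`` over all rule activations.
    """
    mu_cache: dict[tuple[str, int], np.ndarray] = {}

    def membership(label: str, j: int) -> np.ndarray:
        key = (label, j)
        if key not in mu_cache:
            mu_cache[key] = np.asarray(
                config.input_sets[label](delta_arrays[j - 1]), dtype=np.float64
            )
        return mu_cache[key]

    strengths = []
    for rule in config.rules:
        s = None
        for j, label in rule.antecedents:
            mu = membership(label, j)
            s = mu if s is None else np.minimum(s, mu)
        strengths.append(s)

    agg: dict[str, np.ndarray] = {}
    for rule, s in zip(config.rules, strengths):
        if rule.consequent in agg:
            agg[rule.consequent] = np.maximum(agg[rule.consequent], s)
        else:
            agg[rule.consequent] = s

    overall = strengths[0]
    for s in strengths[1:]:
        overall = np.maximum(overall, s)
    implicit_else = 1.0 - overall
    if "NonEdge" in agg:
        agg["NonEdge"] = np.maximum(agg["NonEdge"], implicit_else)
    else:
        agg["NonEdge"] = implicit_else
    # Fixed label order keeps scalar and image paths numerically identical.
    ordered = {}
    for label in sorted(agg):
        ordered[label] = agg[label]
    return ordered


def edge_score(deltas, config: DetectorConfig | None = None) -> float:
    """Crisp edge score (grey level) for one delta neighbourhood."""
    config = config or DetectorConfig()
    deltas = np.asarray(deltas, dtype=np.float64)
    if deltas.shape != (8,):
        raise ValueError(f"expected 8 deltas, got shape {deltas.shape}")
    arrays = [deltas[j : j + 1] for j in range(8)]
    agg = _edge_aggregates(arrays, config)
    c = defuzzify_batch(
        agg, config.output_sets, config.universe, fallback=config.nonedge_center
    )
    return float(c[0])


def score_map(image, config: DetectorConfig | None = None) -> np.ndarray:
    """Edge-score raster; the 1-pixel border carries the no-evidence score."""
    config = config or DetectorConfig()
    arr = _validate_image(image)
    m, n = arr.shape
    center = arr[1:-1, 1:-1]
    planes = []
    for name in config.neighbor_order:
        dr, dc = NEIGHBOR_OFFSETS[name]
        neighbour = arr[1 + dr : m - 1 + dr, 1 + dc : n - 1 + dc]
        planes.append(np.abs(neighbour - center))
    agg = _edge_aggregates(planes, config)
    flat = {lab: a.ravel() for lab, a in agg.items()}
    c = defuzzify_batch(
        flat, config.output_sets, config.universe, fallback=config.nonedge_center
    )
    border_score = edge_score(np.zeros(8), config)
    scores = np.full((m, n), border_score, dtype=np.float64)
    scores[1:-1, 1:-1] = c.reshape(m - 2, n - 2)
    return scores


def detect_edges(
    image, config: DetectorConfig | None = None, return_scores: bool = False
):
    """Binary edge map: interior pixels whose edge score reaches the threshold.

    The outermost 1-pixel frame is never flagged — no padding is invented at
    the image border.
    """
    config = config or DetectorConfig()
    scores = score_map(image, config)
    edges = np.zeros(scores.shape, dtype=bool)
    edges[1:-1, 1:-1] = scores[1:-1, 1:-1] >= config.threshold
    if return_scores:
        return edges, scores
    return edges
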