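"""Mamdani fuzzy-inference primitives.

This module implements the small fuzzy-logic engine shared by the edge
detector and the contrast-intensification stage: membership functions on the
8-bit grey-level universe, labelled fuzzy sets, rules with don't-care
antecedents, min/max Mamdani inference, and discretized centroid
defuzzification.

Conventions
-----------
* A *membership function* maps a grey level ``w`` to a degree in ``[0, 1]``.
* Rules combine antecedent degrees with the **min** t-norm; rules sharing a
  consequent are aggregated with **max**; a consequent set is *clipped* at
  its aggregate strength before the clipped sets are merged pointwise by max
  over a sampled output universe.
* The crisp output is the centroid of the merged membership profile,

      c = sum_x q_x * z_x / sum_x q_x,

  where ``z_x`` are the universe samples and ``q_x`` the aggregated degrees.

All evaluation routines are NumPy-vectorized; scalar entry points route
through the same array code so that per-pixel and whole-image computations
are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "TrapezoidalMF",
    "GaussianMF",
    "FuzzySet",
    "FuzzyRule",
    "OutputUniverse",
    "eval_mf",
    "firing_strength",
    "aggregate_strengths",
    "defuzzify",
    "defuzzify_batch",
    "infer_and_defuzzify",
    "mf_center",
]


@dataclass(frozen=True)
class TrapezoidalMF:
    """Trapezoidal membership function with breakpoints ``r <= s <= t <= u``.

    The degree is 0 outside ``[r, u]``, 1 on the plateau ``[s, t]`` and
    linear on the two ramps.  Degenerate ramps (``r == s`` or ``t == u``)
    collapse to a step at the plateau edge.
    """

    r: float
    s: float
    t: float
    u: float

    def __post_init__(self) -> None:
        if not (self.r <= self.s <= self.t <= self.u):
            raise ValueError(
                f"trapezoid breakpoints must satisfy r <= s <= t <= u, "
                f"got ({self.r}, {self.s}, {self.t}, {self.u})"
            )
        if not all(np.isfinite([self.r, self.s, self.t, self.u])):
            raise ValueError("trapezoid breakpoints must be finite")

    def __call__(self, w):
        w = np.asarray(w, dtype=np.float64)
        out = np.ones_like(w)
        if self.s > self.r:
            rising = (w - self.r) / (self.s - self.r)
            out = np.where(w < self.s, rising, out)
        if self.u > self.t:
            falling = (self.u - w) / (self.u - self.t)
            out = np.where(w > self.t, falling, out)
        out = np.where((w < self.r) | (w > self.u), 0.0, out)
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function ``exp(-(w - m)^2 / (2 d^2))``.

    ``m`` is the centre (the only grey level with degree exactly 1) and
    ``d > 0`` the width; the degree is strictly positive everywhere.
    """

    m: float
    d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m) and np.isfinite(self.d)):
            raise ValueError("Gaussian parameters must be finite")
        if self.d <= 0:
            raise ValueError(f"Gaussian width d must be positive, got {self.d}")

    def __call__(self, w):
        w = np.asarray(w, dtype=np.float64)
        z = (w - self.m) / self.d
        return np.exp(-0.5 * z * z)


MembershipFunction = Union[TrapezoidalMF, GaussianMF]


def mf_center(mf: MembershipFunction) -> float:
    """Grey level at which the membership function peaks.

    For a trapezoid this is the midpoint of the plateau; for a Gaussian the
    centre ``m``.
    """
    if isinstance(mf, GaussianMF):
        return float(mf.m)
    return float((mf.s + mf.t) / 2.0)


@dataclass(frozen=True)
class FuzzySet:
    """A labelled membership function restricted to a finite universe.

    Evaluation outside the universe is clamped to the boundary degree, so a
    fuzzy set never extrapolates beyond its support interval.
    """

    label: str
    mf: MembershipFunction
    universe: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"universe bounds must be finite and ordered, got {self.universe}")

    def __call__(self, w):
        lo, hi = self.universe
        return self.mf(np.clip(np.asarray(w, dtype=np.float64), lo, hi))


@dataclass(frozen=True)
class FuzzyRule:
    """One linguistic rule: a partial antecedent pattern and a consequent.

    ``antecedents`` maps 1-based input indices to input-set labels; indices
    absent from the mapping are don't-care and never enter the t-norm.
    """

    antecedents: tuple[tuple[int, str], ...]
    consequent: str
    n_inputs: int = 8

    def __init__(
        self,
        antecedents: Mapping[int, str] | Iterable[tuple[int, str]],
        consequent: str,
        n_inputs: int = 8,
    ) -> None:
        if isinstance(antecedents, Mapping):
            pairs = tuple(sorted(antecedents.items()))
        else:
            pairs = tuple(sorted(antecedents))
        if not pairs:
            raise ValueError("a rule needs at least one specified antecedent")
        for j, label in pairs:
            if not (1 <= j <= n_inputs):
                raise ValueError(f"antecedent index {j} outside 1..{n_inputs}")
            if not isinstance(label, str):
                raise TypeError("antecedent labels must be strings")
        object.__setattr__(self, "antecedents", pairs)
        object.__setattr__(self, "consequent", consequent)
        object.__setattr__(self, "n_inputs", n_inputs)

    @classmethod
    def from_text(cls, text: str, n_inputs: int = 8) -> "FuzzyRule":
        """Parse ``"1:Higher 2:Higher 8:Lower => Edge"``.

        Single-letter label abbreviations (``H``, ``L``) expand to
        ``Higher`` / ``Lower``.
        """
        if "=>" not in text:
            raise ValueError(f"rule text {text!r} lacks '=>'")
        lhs, rhs = text.split("=>", 1)
        expand = {"H": "Higher", "L": "Lower"}
        ants: dict[int, str] = {}
        for token in lhs.split():
            if ":" not in token:
                raise ValueError(f"bad antecedent token {token!r}")
            idx, label = token.split(":", 1)
            label = expand.get(label, label)
            ants[int(idx)] = label
        return cls(ants, rhs.strip(), n_inputs=n_inputs)


@dataclass
class OutputUniverse:
    """Evenly spaced sample grid on the crisp output interval ``[lo, hi]``."""

    lo: float = 0.0
    hi: float = 255.0
    n: int = 256
    points: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("output universe needs at least two samples")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError("output universe bounds must be finite and ordered")
        self.points = np.linspace(self.lo, self.hi, self.n)


def eval_mf(fset: FuzzySet, w):
    """Degree of membership of grey level(s) ``w`` in ``fset``."""
    return fset(w)


def firing_strength(rule: FuzzyRule, values, input_sets: Mapping[str, FuzzySet]):
    """Min-t-norm rule activation over the specified antecedents only.

    ``values`` holds the inputs indexed 1..n (a length-n sequence or, for
    vectorized use, a sequence of equal-shaped arrays); don't-care inputs do
    not participate.
    """
    strength = None
    for j, label in rule.antecedents:
        mu = input_sets[label](values[j - 1])
        strength = mu if strength is None else np.minimum(strength, mu)
    return strength


def aggregate_strengths(
    rules: Sequence[FuzzyRule], strengths: Sequence
) -> dict[str, np.ndarray]:
    """Max-aggregate per-rule strengths by consequent label."""
    if len(rules) != len(strengths):
        raise ValueError("rules and strengths differ in length")
    agg: dict[str, np.ndarray] = {}
    for rule, s in zip(rules, strengths):
        s = np.asarray(s, dtype=np.float64)
        if rule.consequent in agg:
            agg[rule.consequent] = np.maximum(agg[rule.consequent], s)
        else:
            agg[rule.consequent] = s
    return agg


def defuzzify_batch(
    aggregates: Mapping[str, np.ndarray],
    output_sets: Mapping[str, FuzzySet],
    universe: OutputUniverse,
    fallback: float | None = None,
    chunk: int = 8192,
) -> np.ndarray:
    """Centroid-defuzzify a batch of aggregate-strength profiles.

    Each consequent membership curve is clipped at its aggregate strength,
    the clipped curves are merged pointwise by max over the universe samples,
    and the centroid of the merged profile is returned per batch element.
    Where the merged profile is identically zero the ``fallback`` value is
    used (an error is raised if none was given).
    """
    z = universe.points
    labels = list(aggregates)
    arrays = [np.asarray(aggregates[lab], dtype=np.float64).ravel() for lab in labels]
    size = arrays[0].size
    for a in arrays:
        if a.size != size:
            raise ValueError("aggregate strength arrays must share a shape")
    mus = [np.asarray(output_sets[lab](z), dtype=np.float64) for lab in labels]

    out = np.empty(size, dtype=np.float64)
    for start in range(0, size, chunk):
        stop = min(start + chunk, size)
        q = None
        for a, mu in zip(arrays, mus):
            clipped = np.minimum(mu[None, :], a[start:stop, None])
            q = clipped if q is None else np.maximum(q, clipped)
        num = (q * z).sum(axis=1)
        den = q.sum(axis=1)
        empty = den == 0.0
        if np.any(empty):
            if fallback is None:
                raise ValueError("aggregate profile is identically zero and no fallback given")
            den = np.where(empty, 1.0, den)
            num = np.where(empty, float(fallback), num)
        out[start:stop] = num / den
    return out


def defuzzify(
    aggregates: Mapping[str, float],
    output_sets: Mapping[str, FuzzySet],
    universe: OutputUniverse,
    fallback: float | None = None,
) -> float:
    """Scalar centroid defuzzification (routes through the batch kernel)."""
    batched = {lab: np.asarray([val], dtype=np.float64) for lab, val in aggregates.items()}
    return float(defuzzify_batch(batched, output_sets, universe, fallback=fallback)[0])


def infer_and_defuzzify(
    rules: Sequence[FuzzyRule],
    strengths: Sequence[float],
    output_sets: Mapping[str, FuzzySet],
    universe: OutputUniverse,
    fallback: float | None = None,
) -> float:
    """Aggregate per-rule strengths by consequent, then defuzzify."""
    agg = aggregate_strengths(rules, strengths)
    scalar = {lab: float(np.asarray(v)) for lab, v in agg.items()}
    return defuzzify(scalar, output_sets, universe, fallback=fallback)
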