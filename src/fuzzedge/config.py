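"""Plain-text configuration files for the detector, contrast and noise stages.

The format is INI-style with ``[detector]``, ``[contrast]`` and ``[noise]``
sections; membership functions are written as either four numbers (a
trapezoid ``r s t u``) or ``gaussian m d``, and the rule table as
semicolon-separated rules like ``1:Higher 2:Higher 8:Lower => Edge``.
Omitted keys and sections fall back to the built-in default profile (the
published parameter tables of the method).

Example::

    [detector]
    lower = 0 0 25 75
    higher = 25 75 255 255
    edge = gaussian 245 3.5
    nonedge = gaussian 10 3.5
    threshold = 127.5
    universe_n = 256
    neighbor_order = NW N NE W E SW S SE
    rules = 1:H 2:H 8:L => Edge ; 1:H 4:H 8:L => Edge

    [contrast]
    darker = 0 0 60 140
    grey_in = 90 125 130 165
    brighter = 115 195 255 255
    darkest = gaussian 5 15
    grey_out = gaussian 127.5 15
    brightest = gaussian 250 15

    [noise]
    psnr_db = 25
    tol_db = 0.25
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .contrast import ContrastConfig
from .detector import DetectorConfig
from .fuzzy_core import (
    FuzzyRule,
    FuzzySet,
    GaussianMF,
    OutputUniverse,
    TrapezoidalMF,
)

__all__ = ["parse_mf", "parse_rules", "load_config", "RunSettings"]


def parse_mf(text: str):
    """Parse ``"r s t u"``, ``"trap r s t u"`` or ``"gaussian m d"``."""
    tokens = text.replace(",", " ").split()
    if not tokens:
        raise ValueError("empty membership-function specification")
    kind = tokens[0].lower()
    if kind in ("gaussian", "gauss"):
        m, d = (float(v) for v in tokens[1:3])
        return GaussianMF(m=m, d=d)
    if kind in ("trap", "trapezoid", "tmf"):
        tokens = tokens[1:]
    values = [float(v) for v in tokens]
    if len(values) == 2:
        return GaussianMF(m=values[1], d=values[0])
    if len(values) != 4:
        raise ValueError(f"cannot parse membership function from {text!r}")
    return TrapezoidalMF(*values)


def parse_rules(text: str, n_inputs: int = 8) -> tuple[FuzzyRule, ...]:
    """Parse a semicolon-separated rule list."""
    rules = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            rules.append(FuzzyRule.from_text(chunk, n_inputs=n_inputs))
    if not rules:
        raise ValueError("rule table is empty")
    return tuple(rules)


class RunSettings:
    """Parsed configuration: stage configs plus noise parameters."""

    def __init__(
        self,
        detector: DetectorConfig,
        contrast: ContrastConfig,
        psnr_db: float = 25.0,
        tol_db: float = 0.25,
    ) -> None:
        self.detector = detector
        self.contrast = contrast
        self.psnr_db = psnr_db
        self.tol_db = tol_db


def _fset(label: str, section, key: str, default):
    if section is not None and key in section:
        return FuzzySet(label, parse_mf(section[key]))
    return default


def load_config(path=None) -> RunSettings:
    """Load a config file; a missing path yields the default profile."""
    parser = configparser.ConfigParser()
    if path is not None:
        read = parser.read(Path(path))
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")

    det = DetectorConfig()
    sec = parser["detector"] if parser.has_section("detector") else None
    if sec is not None:
        input_sets = {
            "Lower": _fset("Lower", sec, "lower", det.input_sets["Lower"]),
            "Higher": _fset("Higher", sec, "higher", det.input_sets["Higher"]),
        }
        output_sets = {
            "NonEdge": _fset("NonEdge", sec, "nonedge", det.output_sets["NonEdge"]),
            "Edge": _fset("Edge", sec, "edge", det.output_sets["Edge"]),
        }
        rules = parse_rules(sec["rules"]) if "rules" in sec else det.rules
        universe = OutputUniverse(n=sec.getint("universe_n", det.universe.n))
        order = tuple(sec["neighbor_order"].split()) if "neighbor_order" in sec else det.neighbor_order
        det = DetectorConfig(
            input_sets=input_sets,
            output_sets=output_sets,
            rules=rules,
            universe=universe,
            threshold=sec.getfloat("threshold", det.threshold),
            neighbor_order=order,
        )

    con = ContrastConfig()
    sec = parser["contrast"] if parser.has_section("contrast") else None
    if sec is not None:
        input_sets = {
            "Darker": _fset("Darker", sec, "darker", con.input_sets["Darker"]),
            "Grey": _fset("Grey", sec, "grey_in", con.input_sets["Grey"]),
            "Brighter": _fset("Brighter", sec, "brighter", con.input_sets["Brighter"]),
        }
        output_sets = {
            "Darkest": _fset("Darkest", sec, "darkest", con.output_sets["Darkest"]),
            "Grey": _fset("Grey", sec, "grey_out", con.output_sets["Grey"]),
            "Brightest": _fset("Brightest", sec, "brightest", con.output_sets["Brightest"]),
        }
        universe = OutputUniverse(n=sec.getint("universe_n", con.universe.n))
        con = ContrastConfig(input_sets=input_sets, output_sets=output_sets, universe=universe)

    psnr_db, tol_db = 25.0, 0.25
    if parser.has_section("noise"):
        sec = parser["noise"]
        psnr_db = sec.getfloat("psnr_db", psnr_db)
        tol_db = sec.getfloat("tol_db", tol_db)

    return RunSettings(detector=det, contrast=con, psnr_db=psnr_db, tol_db=tol_db)
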