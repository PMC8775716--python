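"""Hierarchical assembly model: predicted fibril heights and peak labels.

A composition like ``"4 + 1"`` names the protofilament counts of the
sub-filaments intertwined in a fibril.  Three packing rules convert a
composition into a predicted ridge height from the base protofilament
height ``h1``:

- ``sqrt_n``: a composition totalling n protofilaments has height h1*sqrt(n);
- ``pythagorean``: h(a+b) = sqrt(h(a)^2 + h(b)^2) with leaf h(a) = h1*sqrt(a);
- ``additive``: h(a+b) = h(a) + h(b) with leaf h(a) = h1*a.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .histogram import PeakMixtureFit

__all__ = [
    "AssemblyModel",
    "FibrilAssignment",
    "parse_composition",
    "predict_heights",
    "assign_fibril_types",
]

_RULES = ("sqrt_n", "pythagorean", "additive")

SUB_PROTOFILAMENT = "sub-protofilament"


@dataclass(frozen=True)
class AssemblyModel:
    """Base protofilament height and packing rule."""

    h1: float
    rule: str = "sqrt_n"

    def __post_init__(self):
        if self.h1 <= 0:
            raise ValueError("h1 must be positive")
        if self.rule not in _RULES:
            raise ValueError(f"unknown packing rule {self.rule!r}; choose from {_RULES}")


@dataclass
class FibrilAssignment:
    """One histogram peak labelled with its nearest composition(s)."""

    peak_mean: float
    labels: list[str]
    predicted: list[float]


def parse_composition(text: str) -> list[int]:
    """Parse ``"a + b"`` into sub-filament protofilament counts."""
    parts = [p.strip() for p in re.split(r"\+", text)]
    if not parts or any(not re.fullmatch(r"\d+", p) for p in parts):
        raise ValueError(f"cannot parse composition {text!r}; expected e.g. '4 + 1'")
    counts = [int(p) for p in parts]
    if any(c < 1 for c in counts):
        raise ValueError("protofilament counts must be >= 1")
    return counts


def _predict_one(model: AssemblyModel, counts: list[int]) -> float:
    if model.rule == "sqrt_n":
        return model.h1 * float(np.sqrt(sum(counts)))
    if model.rule == "pythagorean":
        leaf = [model.h1 * np.sqrt(c) for c in counts]
        return float(np.sqrt(sum(h * h for h in leaf)))
    # additive
    return model.h1 * float(sum(counts))


def predict_heights(model: AssemblyModel, compositions: list[str]) -> list[float]:
    """Predicted ridge height (nm) for each composition string."""
    return [_predict_one(model, parse_composition(c)) for c in compositions]


DEFAULT_COMPOSITIONS = ["1", "1 + 1", "2 + 1", "2 + 2", "4 + 1", "4 + 4", "8 + 1", "8 + 8"]


def assign_fibril_types(
    mix: PeakMixtureFit,
    model: AssemblyModel,
    candidate_compositions: list[str] | None = None,
    tie_tolerance: float = 0.25,
) -> list[FibrilAssignment]:
    """Label each mixture peak with the nearest-height composition(s).

    Compositions whose predicted heights are within ``tie_tolerance`` nm of
    the best match are all reported (multi-label peaks).  Peaks below half
    the protofilament height get the sub-protofilament label with a warning.
    """
    if candidate_compositions is None:
        candidate_compositions = list(DEFAULT_COMPOSITIONS)
    preds = predict_heights(model, candidate_compositions)
    out = []
    for mean in mix.means:
        if mean < model.h1 / 2.0:
            warnings.warn(
                f"peak at {mean:.2f} nm is below half the protofilament height"
            )
            out.append(FibrilAssignment(peak_mean=mean, labels=[SUB_PROTOFILAMENT], predicted=[]))
            continue
        dists = [abs(p - mean) for p in preds]
        dmin = min(dists)
        labels, predicted = [], []
        for comp, p, d in zip(candidate_compositions, preds, dists):
            if d <= dmin + tie_tolerance:
                labels.append(comp)
                predicted.append(p)
        out.append(FibrilAssignment(peak_mean=mean, labels=labels, predicted=predicted))
    return out
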