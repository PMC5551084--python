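"""Dominant benthic class per quadrat from area-proportion annotations.

Quadrats are annotated with the fraction of area covered by each benthic
class (sand, abiotic/mixed hard bottom, and four coral morphotypes). A quadrat
is assigned its highest-proportion class when that proportion exceeds 25%;
otherwise it is "Mixed". For the error regressions the non-coral classes are
pooled into the "Mixed" base category, leaving the four coral morphotypes as
categorical levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "BENTHIC_CLASSES",
    "CORAL_MORPHOTYPES",
    "MODEL_LEVELS",
    "MIXED",
    "BenthicComposition",
    "DominantClass",
    "assign_dominant",
    "assign_dominant_table",
    "pool_for_model",
]

#: annotated benthic classes, in the fixed tie-break order
BENTHIC_CLASSES = (
    "Sand",
    "Abiotic/Mixed Hard Bottom",
    "Massives",
    "Plating",
    "Fine-Branching",
    "Coarse Branching",
)

CORAL_MORPHOTYPES = ("Massives", "Plating", "Fine-Branching", "Coarse Branching")

MIXED = "Mixed"

#: categorical levels entering the error model (Mixed is the base category)
MODEL_LEVELS = (MIXED,) + CORAL_MORPHOTYPES

DOMINANCE_THRESHOLD = 0.25


@dataclass
class BenthicComposition:
    """Area proportions of the benthic classes within one quadrat."""

    quadrat_id: int
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(BENTHIC_CLASSES)
        if unknown:
            raise ParameterError(f"unknown benthic class(es): {sorted(unknown)}")
        vals = np.array([self.proportions.get(c, 0.0) for c in BENTHIC_CLASSES])
        if np.any(vals < 0) or np.any(vals > 1):
            raise ParameterError("proportions must lie in [0, 1]")
        if vals.sum() > 1 + 1e-6:
            raise ParameterError(f"proportions sum to {vals.sum():.4f} > 1")


@dataclass
class DominantClass:
    quadrat_id: int
    label: str


def assign_dominant(
    comp: BenthicComposition, threshold: float = DOMINANCE_THRESHOLD
) -> DominantClass:
    """Dominant-class label: argmax class if its proportion is strictly above
    ``threshold``, else "Mixed". Ties at the maximum are broken by the fixed
    order of :data:`BENTHIC_CLASSES` with a warning."""
    props = np.array([comp.proportions.get(c, 0.0) for c in BENTHIC_CLASSES])
    top = props.max() if props.size else 0.0
    if top <= threshold:  # strict '>' required for dominance
        return DominantClass(comp.quadrat_id, MIXED)
    winners = np.nonzero(props == top)[0]
    if len(winners) > 1:
        warnings.warn(
            f"quadrat {comp.quadrat_id}: dominance tie between "
            f"{[BENTHIC_CLASSES[i] for i in winners]}; taking the first by class order",
            stacklevel=2,
        )
    return DominantClass(comp.quadrat_id, BENTHIC_CLASSES[winners[0]])


def assign_dominant_table(
    table: pd.DataFrame, threshold: float = DOMINANCE_THRESHOLD
) -> pd.DataFrame:
    """Vector form: a DataFrame with quadrat_id + one column per benthic class
    gains a ``dominant_label`` column."""
    out = table.copy()
    labels = []
    for _, row in table.iterrows():
        comp = BenthicComposition(
            int(row["quadrat_id"]),
            {c: float(row[c]) for c in BENTHIC_CLASSES if c in table.columns},
        )
        labels.append(assign_dominant(comp, threshold).label)
    out["dominant_label"] = labels
    return out


def pool_for_model(label: str) -> str:
    """Map a dominant-class label onto the error-model levels.

    Sand and abiotic/mixed hard bottom quadrats are pooled into the "Mixed"
    base category; coral morphotypes pass through.
    """
    if label in CORAL_MORPHOTYPES or label == MIXED:
        return MIXED if label == MIXED else label
    if label in BENTHIC_CLASSES:  # Sand, Abiotic/Mixed Hard Bottom
        return MIXED
    raise ParameterError(f"unknown dominant label {label!r}")
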