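"""Proportion panels and rostral-proportion ecomorph classification.

Converts raw endocast/labyrinth measurements into the eleven dimensionless
ratios used to compare relative proportions across crocodyliforms, and
assigns Busbey-style skull classes (brevirostrine / mesorostrine /
longirostrine) from the rostrum:skull length ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .core_model import (
    Dataset,
    EndocastMeasurements,
    SkullMorphology,
    ValidationError,
)

__all__ = [
    "RatioPanel",
    "SkullClass",
    "RATIO_DEFINITIONS",
    "compute_ratio_panel",
    "classify_skull",
    "classify_dataset",
    "display_round",
    "BREVI_MESO_THRESHOLD",
    "MESO_LONGI_THRESHOLD",
]

#: ratio name -> (numerator field, denominator field) on EndocastMeasurements.
#: ``pituitary_length_to_hindcast_length`` divides by the hindcast length
#: (endocast length minus olfactory tract length) and is handled separately.
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "cerebrum_width_to_skull_width": ("cerebrum_width", "skull_width_at_cerebrum"),
    "cerebrum_width_to_endocast_length": ("cerebrum_width", "endocast_length"),
    "olfactory_tract_to_endocast_length": ("olfactory_tract_length", "endocast_length"),
    "pituitary_width_to_height": ("pituitary_width", "pituitary_height"),
    "pituitary_width_to_length": ("pituitary_width", "pituitary_length"),
    "labyrinth_width_to_height": ("labyrinth_width", "labyrinth_height"),
    "cochlear_duct_to_labyrinth_height": ("cochlear_duct_length", "labyrinth_height"),
    "asc_to_psc_area": ("asc_area", "psc_area"),
    "asc_to_lsc_area": ("asc_area", "lsc_area"),
    "psc_to_lsc_area": ("psc_area", "lsc_area"),
}


@dataclass
class RatioPanel:
    """The eleven dimensionless proportion ratios; missing iff an operand is."""

    cerebrum_width_to_skull_width: Optional[float] = None
    cerebrum_width_to_endocast_length: Optional[float] = None
    olfactory_tract_to_endocast_length: Optional[float] = None
    pituitary_width_to_height: Optional[float] = None
    pituitary_width_to_length: Optional[float] = None
    pituitary_length_to_hindcast_length: Optional[float] = None
    labyrinth_width_to_height: Optional[float] = None
    cochlear_duct_to_labyrinth_height: Optional[float] = None
    asc_to_psc_area: Optional[float] = None
    asc_to_lsc_area: Optional[float] = None
    psc_to_lsc_area: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        """Display form: unrounded values rendered at ``ndigits`` decimals."""
        return {
            k: (None if v is None else display_round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def display_round(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compute_ratio_panel(m: EndocastMeasurements) -> RatioPanel:
    """Compute the proportion panel from one specimen's measurements.

    Missing operands propagate to missing ratios; values are retained
    unrounded (use :meth:`RatioPanel.rounded` for 2-decimal display).
    """
    m.validate()
    panel = RatioPanel()
    for name, (num, den) in RATIO_DEFINITIONS.items():
        a, b = getattr(m, num), getattr(m, den)
        setattr(panel, name, None if a is None or b is None else a / b)
    if (
        m.pituitary_length is not None
        and m.endocast_length is not None
        and m.olfactory_tract_length is not None
    ):
        hindcast = m.endocast_length - m.olfactory_tract_length
        panel.pituitary_length_to_hindcast_length = m.pituitary_length / hindcast
    return panel


BREVI_MESO_THRESHOLD = 0.55
MESO_LONGI_THRESHOLD = 0.70


@dataclass
class SkullClass:
    """An ecomorph assignment with its provenance.

    ``inferred`` marks a class passed through from the source table rather
    than computed from a rostrum ratio; ``consistent_with_asserted`` is False
    when a computed class disagrees with the class asserted in the metadata
    (some published assignments also weigh snout width, so disagreement with
    the pure length-ratio rule is possible and worth surfacing).
    """

    value: SkullMorphology
    rostrum_ratio: Optional[float] = None
    inferred: bool = False
    consistent_with_asserted: bool = True


def classify_skull(rostrum_ratio: float) -> SkullClass:
    """Classify a skull from its rostrum:skull length ratio.

    brevirostrine below 0.55; mesorostrine on the closed interval
    [0.55, 0.70]; longirostrine above 0.70.
    """
    if not (0 < rostrum_ratio < 1.5):
        raise ValidationError(
            f"rostrum_ratio must lie in (0, 1.5), got {rostrum_ratio!r}"
        )
    if rostrum_ratio < BREVI_MESO_THRESHOLD:
        value = SkullMorphology.BREVIROSTRINE
    elif rostrum_ratio <= MESO_LONGI_THRESHOLD:
        value = SkullMorphology.MESOROSTRINE
    else:
        value = SkullMorphology.LONGIROSTRINE
    return SkullClass(value=value, rostrum_ratio=rostrum_ratio)


def classify_dataset(dataset: Dataset) -> dict[str, SkullClass]:
    """Classify every specimen in a dataset.

    Computes the class from ``skull_rostrum_ratio`` where present; where the
    ratio is missing, passes through the asserted ``skull_class`` flagged as
    inferred. A record lacking both raises.
    """
    out: dict[str, SkullClass] = {}
    for rec in dataset.records:
        if rec.skull_rostrum_ratio is not None:
            cls = classify_skull(rec.skull_rostrum_ratio)
            if rec.skull_class is not None and rec.skull_class != cls.value:
                cls.consistent_with_asserted = False
        elif rec.skull_class is not None:
            cls = SkullClass(value=rec.skull_class, inferred=True)
        else:
            raise ValidationError(
                f"{rec.specimen_id}: neither skull_rostrum_ratio nor skull_class available"
            )
        out[rec.specimen_id] = cls
    return out
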