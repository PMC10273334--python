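"""Sensory-acuity estimators and the reptile encephalisation quotient (REQ).

Three estimator families:

* **Olfactory acuity** — the greatest diameter of the olfactory bulb relative
  to the greatest diameter of the cerebral hemisphere, expressed on a log
  scale: ``log10(100 * bulb / hemisphere)``. Equal diameters give exactly 2.
* **Relative optic-lobe volume** — the optic lobe as a percentage of the whole
  endocast volume, a proxy for visual acuity where sclerotic rings are absent.
* **REQ chain** — body mass from total skull length via the crocodylian
  allometry ``ln(TL) = a·ln(M) + b`` (defaults a=0.32, b=2.05, TL in mm, M in
  g); brain volume from endocast volume via a fitted linear regression; brain
  mass at 1 g/cm^3; then ``REQ = MBr / (0.0155 · MBd^0.553)``, the observed
  brain mass over that expected for a reptile of equal body mass.

All coefficients are parameters with the published defaults, not constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import Dataset, ValidationError, VolumePanel, load_example_table

__all__ = [
    "ReqCoefficients",
    "BrainRegression",
    "SensoryReport",
    "olfactory_ratio",
    "optic_fraction",
    "body_mass_from_skull_length",
    "skull_length_from_body_mass",
    "fit_brain_regression",
    "default_brain_regression",
    "req",
    "sensory_report",
    "sensory_report_table",
]


@dataclass(frozen=True)
class ReqCoefficients:
    """Allometry and REQ coefficients (published crocodylian defaults)."""

    allometry_slope: float = 0.32
    allometry_intercept: float = 2.05
    req_scale: float = 0.0155
    req_exponent: float = 0.553
    brain_density_g_per_cm3: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "allometry_slope",
            "allometry_intercept",
            "req_scale",
            "req_exponent",
            "brain_density_g_per_cm3",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class BrainRegression:
    """OLS fit of brain volume (cm^3) on endocast volume (cm^3)."""

    slope: float
    intercept: float
    n: int
    r_squared: float
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")

    def predict(self, endocast_volume_cm3: float) -> float:
        return self.slope * endocast_volume_cm3 + self.intercept


@dataclass
class SensoryReport:
    """Per-specimen output of the acuity / encephalisation chain."""

    olfactory_ratio: Optional[float] = None
    optic_fraction_percent: Optional[float] = None
    brain_volume_cm3: Optional[float] = None
    brain_mass_g: Optional[float] = None
    body_mass_g: Optional[float] = None
    req: Optional[float] = None


def olfactory_ratio(
    bulb_diameter: float,
    hemisphere_diameter: float,
    *,
    percentage_factor: float = 100.0,
    log_base: float = 10.0,
) -> float:
    """Log-scaled olfactory bulb : cerebral hemisphere diameter ratio.

    Default form ``log10(100 * bulb / hemisphere)``; equal diameters give
    exactly 2. Strictly increasing in the bulb diameter, decreasing in the
    hemisphere diameter, and invariant to common rescaling of both.
    """
    if not (bulb_diameter > 0 and hemisphere_diameter > 0):
        raise ValidationError("diameters must be positive")
    return math.log(percentage_factor * bulb_diameter / hemisphere_diameter, log_base)


def optic_fraction(optic_volume_mm3: float, endocast_volume_mm3: float) -> float:
    """Optic-lobe volume as a percentage of the whole endocast volume."""
    if not endocast_volume_mm3 > 0:
        raise ValidationError("endocast volume must be positive")
    if optic_volume_mm3 < 0:
        raise ValidationError("optic volume must be non-negative")
    if optic_volume_mm3 > endocast_volume_mm3:
        raise ValidationError("optic volume exceeds endocast volume")
    return 100.0 * optic_volume_mm3 / endocast_volume_mm3


def body_mass_from_skull_length(
    total_skull_length_mm: float, c: ReqCoefficients = ReqCoefficients()
) -> float:
    """Body mass (g) from total skull length (mm): (TL·e^-b)^(1/a)."""
    if not total_skull_length_mm > 0:
        raise ValidationError("skull length must be positive")
    return (total_skull_length_mm * math.exp(-c.allometry_intercept)) ** (
        1.0 / c.allometry_slope
    )


def skull_length_from_body_mass(
    body_mass_g: float, c: ReqCoefficients = ReqCoefficients()
) -> float:
    """Inverse allometry: TL (mm) = exp(a·ln(M) + b)."""
    if not body_mass_g > 0:
        raise ValidationError("body mass must be positive")
    return math.exp(c.allometry_slope * math.log(body_mass_g) + c.allometry_intercept)


def fit_brain_regression(
    pairs: Sequence[tuple[float, float]]
) -> BrainRegression:
    """Ordinary least squares of brain volume on endocast volume (both cm^3)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need >= 2 (endocast, brain) volume pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValidationError("degenerate design: all endocast volumes equal")
    res = stats.linregress(x, y)
    return BrainRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def default_brain_regression() -> BrainRegression:
    """Brain-volume regression refitted from the packaged nine-specimen
    crocodyliform (endocast, brain) volume panel."""
    ds = load_example_table("table6")
    pairs = [
        (v.endocast_volume_mm3 / 1000.0, v.brain_volume_cm3)
        for v in ds.volumes.values()
        if v.endocast_volume_mm3 is not None and v.brain_volume_cm3 is not None
    ]
    return fit_brain_regression(pairs)


def req(
    brain_mass_g: float, body_mass_g: float, c: ReqCoefficients = ReqCoefficients()
) -> float:
    """Reptile encephalisation quotient: MBr / (scale · MBd^exponent)."""
    if not (brain_mass_g > 0 and body_mass_g > 0):
        raise ValidationError("masses must be positive")
    return brain_mass_g / (c.req_scale * body_mass_g**c.req_exponent)


def sensory_report(
    v: VolumePanel,
    reg: Optional[BrainRegression] = None,
    c: ReqCoefficients = ReqCoefficients(),
) -> SensoryReport:
    """Chain the full panel: acuity ratios, brain/body mass, and REQ.

    Brain volume comes from the regression applied to the endocast volume
    (mm^3 converted to cm^3) unless the panel already carries it. Body mass
    is taken as given when present, else derived from total skull length;
    REQ requires both masses.
    """
    v.validate()
    rep = SensoryReport()
    if (
        v.olfactory_bulb_diameter_mm is not None
        and v.cerebral_hemisphere_diameter_mm is not None
    ):
        rep.olfactory_ratio = olfactory_ratio(
            v.olfactory_bulb_diameter_mm, v.cerebral_hemisphere_diameter_mm
        )
    if v.optic_lobe_volume_mm3 is not None and v.endocast_volume_mm3 is not None:
        rep.optic_fraction_percent = optic_fraction(
            v.optic_lobe_volume_mm3, v.endocast_volume_mm3
        )
    if v.brain_volume_cm3 is not None:
        rep.brain_volume_cm3 = v.brain_volume_cm3
    elif v.endocast_volume_mm3 is not None:
        if reg is None:
            reg = default_brain_regression()
        rep.brain_volume_cm3 = reg.predict(v.endocast_volume_mm3 / 1000.0)
    if rep.brain_volume_cm3 is not None:
        rep.brain_mass_g = rep.brain_volume_cm3 * c.brain_density_g_per_cm3
    if v.body_mass_g is not None:
        rep.body_mass_g = v.body_mass_g
    elif v.total_skull_length_mm is not None:
        rep.body_mass_g = body_mass_from_skull_length(v.total_skull_length_mm, c)
    elif rep.brain_mass_g is not None:
        raise ValidationError(
            "neither body_mass_g nor total_skull_length_mm available for REQ"
        )
    if rep.brain_mass_g is not None and rep.body_mass_g is not None:
        rep.req = req(rep.brain_mass_g, rep.body_mass_g, c)
    return rep


def sensory_report_table(
    dataset: Dataset,
    reg: Optional[BrainRegression] = None,
    c: ReqCoefficients = ReqCoefficients(),
) -> dict[str, SensoryReport]:
    """Per-specimen reports for every volume panel in a dataset.

    Panels lacking any mass/skull-length information still yield the acuity
    ratios with REQ left missing.
    """
    out: dict[str, SensoryReport] = {}
    for sid, panel in dataset.volumes.items():
        try:
            out[sid] = sensory_report(panel, reg=reg, c=c)
        except ValidationError:
            rep = SensoryReport()
            if (
                panel.olfactory_bulb_diameter_mm is not None
                and panel.cerebral_hemisphere_diameter_mm is not None
            ):
                rep.olfactory_ratio = olfactory_ratio(
                    panel.olfactory_bulb_diameter_mm,
                    panel.cerebral_hemisphere_diameter_mm,
                )
            if (
                panel.optic_lobe_volume_mm3 is not None
                and panel.endocast_volume_mm3 is not None
            ):
                rep.optic_fraction_percent = optic_fraction(
                    panel.optic_lobe_volume_mm3, panel.endocast_volume_mm3
                )
            out[sid] = rep
    return out
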