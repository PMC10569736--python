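"""Icosahedral capsid geometry and genome packing density.

A tailed-phage capsid is modelled as a regular icosahedron.  TEM protocols
report the diameter of the circle circumscribing the capsid outline, i.e. the
vertex-to-vertex (circumscribed) diameter D.  The DNA-filled cavity is taken
to be a smaller icosahedron whose circumradius is the measured circumradius
minus one uniform shell thickness t:

    R_int = D/2 - t
    V_int = (5/12) (3 + sqrt 5) a^3,   a = 4 R_int / sqrt(10 + 2 sqrt 5)
    density = L / V_int            [bp / nm^3]

Because published capsid diameters do not always use the same radius
convention (vertex circumsphere, edge midsphere, or face insphere),
:func:`radius_convert` converts between the three using the exact icosahedron
ratios.  The shell thickness is rarely printed; :func:`calibrate_thickness`
recovers it from one anchor phage whose packing density is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.optimize import brentq

from .errors import CalibrationError, InvalidGeometryError, InvalidInputError

__all__ = [
    "RadiusConvention",
    "CapsidMeasurement",
    "IcosahedralModel",
    "PackingResult",
    "icosahedron_volume",
    "radius_convert",
    "packing_density",
    "calibrate_thickness",
]

# Exact icosahedron radii in units of the edge length a.
_CIRCUMRADIUS_PER_EDGE = math.sqrt(10.0 + 2.0 * math.sqrt(5.0)) / 4.0  # 0.951056...
_MIDRADIUS_PER_EDGE = (1.0 + math.sqrt(5.0)) / 4.0  # 0.809017...
_INRADIUS_PER_EDGE = math.sqrt(3.0) * (3.0 + math.sqrt(5.0)) / 12.0  # 0.755761...

# Volume coefficient: V = c * a^3 for edge a.
_VOLUME_PER_EDGE3 = (5.0 / 12.0) * (3.0 + math.sqrt(5.0))


class RadiusConvention(str, Enum):
    """Which sphere of the icosahedron a reported radius refers to."""

    CIRCUMSCRIBED = "circumscribed"  # through the 12 vertices
    MIDSPHERE = "midsphere"  # through the 30 edge midpoints
    INSCRIBED = "inscribed"  # through the 20 face centres


_RADIUS_PER_EDGE = {
    RadiusConvention.CIRCUMSCRIBED: _CIRCUMRADIUS_PER_EDGE,
    RadiusConvention.MIDSPHERE: _MIDRADIUS_PER_EDGE,
    RadiusConvention.INSCRIBED: _INRADIUS_PER_EDGE,
}


@dataclass(frozen=True)
class CapsidMeasurement:
    """One phage's TEM-derived capsid size.

    ``circumscribed_diameter`` is the diameter (nm) of the circle
    circumscribing the capsid outline; ``diameter_sd`` its reported standard
    deviation over the measured virions.
    """

    phage_id: str
    circumscribed_diameter: float
    diameter_sd: Optional[float] = None
    tail_length: Optional[float] = None
    n_virions: Optional[int] = None

    def __post_init__(self) -> None:
        if self.circumscribed_diameter <= 0:
            raise InvalidInputError(
                f"{self.phage_id}: circumscribed_diameter must be > 0, "
                f"got {self.circumscribed_diameter}"
            )
        if self.diameter_sd is not None and self.diameter_sd < 0:
            raise InvalidInputError(f"{self.phage_id}: diameter_sd must be >= 0")


@dataclass(frozen=True)
class IcosahedralModel:
    """Shell model: uniform thickness t (nm) and the convention of the input radius."""

    shell_thickness: float
    radius_convention: RadiusConvention = RadiusConvention.CIRCUMSCRIBED

    def __post_init__(self) -> None:
        if self.shell_thickness < 0:
            raise InvalidInputError("shell_thickness must be >= 0")
        if not isinstance(self.radius_convention, RadiusConvention):
            object.__setattr__(
                self, "radius_convention", RadiusConvention(self.radius_convention)
            )


@dataclass(frozen=True)
class PackingResult:
    """Internal cavity geometry and the resulting genome packing density."""

    phage_id: str
    internal_circumradius: float
    internal_volume: float
    density: float
    genome_length: int
    density_low: Optional[float] = None  # at D + SD (larger capsid)
    density_high: Optional[float] = None  # at D - SD (smaller capsid)


def icosahedron_volume(circumradius: float) -> float:
    """Volume of a regular icosahedron with the given circumradius.

    V = (5/12)(3 + sqrt 5) a^3 with edge a = 4R / sqrt(10 + 2 sqrt 5).
    """
    if circumradius < 0:
        raise InvalidInputError(f"circumradius must be >= 0, got {circumradius}")
    edge = circumradius / _CIRCUMRADIUS_PER_EDGE
    return _VOLUME_PER_EDGE3 * edge**3


def radius_convert(
    value: float,
    from_convention: RadiusConvention | str,
    to_convention: RadiusConvention | str,
) -> float:
    """Convert a radius (or diameter — the ratios are identical) between
    icosahedron radius conventions using the exact closed-form ratios."""
    if value < 0:
        raise InvalidInputError(f"radius must be >= 0, got {value}")
    try:
        src = RadiusConvention(from_convention)
        dst = RadiusConvention(to_convention)
    except ValueError as exc:
        raise InvalidInputError(f"unknown radius convention: {exc}") from exc
    return value * _RADIUS_PER_EDGE[dst] / _RADIUS_PER_EDGE[src]


def _internal_circumradius(
    measurement: CapsidMeasurement, model: IcosahedralModel, diameter: float
) -> float:
    d_circ = radius_convert(
        diameter, model.radius_convention, RadiusConvention.CIRCUMSCRIBED
    )
    r_int = d_circ / 2.0 - model.shell_thickness
    if r_int <= 0:
        raise InvalidGeometryError(
            f"{measurement.phage_id}: shell thickness {model.shell_thickness} nm "
            f"leaves no cavity inside diameter {diameter} nm"
        )
    return r_int


def packing_density(
    measurement: CapsidMeasurement,
    model: IcosahedralModel,
    genome_length: int,
) -> PackingResult:
    """Genome packing density of one phage under the shell model.

    The measured diameter is converted to the circumscribed convention, the
    shell thickness subtracted from the radius, and the genome length divided
    by the icosahedral cavity volume.  If the measurement carries an SD the
    density is also evaluated at D ± SD (no distributional assumption).
    """
    if genome_length < 0:
        raise InvalidInputError("genome_length must be >= 0")
    r_int = _internal_circumradius(
        measurement, model, measurement.circumscribed_diameter
    )
    volume = icosahedron_volume(r_int)
    density = genome_length / volume
    density_low = density_high = None
    if measurement.diameter_sd:
        d, sd = measurement.circumscribed_diameter, measurement.diameter_sd
        density_low = genome_length / icosahedron_volume(
            _internal_circumradius(measurement, model, d + sd)
        )
        density_high = genome_length / icosahedron_volume(
            _internal_circumradius(measurement, model, d - sd)
        )
    return PackingResult(
        phage_id=measurement.phage_id,
        internal_circumradius=r_int,
        internal_volume=volume,
        density=density,
        genome_length=genome_length,
        density_low=density_low,
        density_high=density_high,
    )


def calibrate_thickness(
    anchor: CapsidMeasurement,
    genome_length: int,
    target_density: float,
    bounds: tuple[float, float] = (0.0, 10.0),
    convention: RadiusConvention | str = RadiusConvention.CIRCUMSCRIBED,
    tol: float = 1e-6,
) -> float:
    """Shell thickness (nm) at which the anchor phage attains ``target_density``.

    Density is strictly increasing in t (smaller cavity, same genome), so the
    root is unique when it is bracketed by ``bounds``.
    """
    if target_density <= 0:
        raise InvalidInputError("target_density must be > 0")
    lo, hi = bounds
    if not 0 <= lo < hi:
        raise InvalidInputError(f"invalid bounds {bounds}")

    def objective(t: float) -> float:
        model = IcosahedralModel(shell_thickness=t, radius_convention=convention)
        return packing_density(anchor, model, genome_length).density - target_density

    try:
        f_lo, f_hi = objective(lo), objective(hi)
    except InvalidGeometryError as exc:
        raise CalibrationError(
            f"bounds {bounds} exceed the capsid radius of {anchor.phage_id}"
        ) from exc
    if f_lo == 0.0:
        return lo
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target density {target_density} not bracketed over thickness "
            f"bounds {bounds} (density range "
            f"[{f_lo + target_density:.4g}, {f_hi + target_density:.4g}])"
        )
    return float(brentq(objective, lo, hi, xtol=tol))
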