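"""Sagittal cervical alignment variables from digitized landmarks.

Implements the posterior-tangent (Harrison) rotational measures and the
segmental Cobb/translation measures used in lateral cervical radiographic
mensuration:

* **ARA** — absolute rotation angle, the global cervical curve: the angle
  between the posterior body tangents of C2 and C7.
* **RRA** (x5) — relative rotation angle per motion segment: the angle
  between posterior body tangents of adjacent vertebrae.
* **KA** (x5) — segmental Cobb angle: the angle between the facing endplate
  lines across each disc (inferior endplate of the upper vertebra vs the
  superior endplate of the lower).
* **ST** (x5) — segmental translation: the signed perpendicular offset of the
  upper vertebra's posterior-inferior corner from the lower vertebra's
  posterior tangent line (a George's-line step-off; anterior positive).
* **C1H** — atlas plane angle relative to true horizontal.
* **TR** — anterior head translation: horizontal offset of the C2
  posterior-superior corner from a vertical line through the C7
  posterior-inferior corner.

Sign convention
---------------
Angles are counterclockwise-positive in the x-anterior/y-superior frame,
which makes extension (lordotic contribution) positive for ARA/RRA/KA and
anterior translation positive for ST/TR. All angles are reported in
(-180, 180] degrees; anatomical values are far from the wrap-around.

With this shared convention the five RRAs telescope exactly:
``ARA = RRA23 + RRA34 + RRA45 + RRA56 + RRA67``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .landmarks import (
    CERVICAL_LEVELS,
    LEVEL_PAIRS,
    AtlasLandmarks,
    LandmarkSet,
    MeasurementVector,
    Point2D,
    StudySet,
    VertebraQuad,
    measurements_to_frame,
)

__all__ = [
    "DegenerateGeometryError",
    "DirectedLine",
    "signed_angle",
    "posterior_tangent",
    "endplate_line",
    "compute_rra",
    "compute_ara",
    "compute_ka",
    "compute_st",
    "compute_c1h",
    "compute_tr",
    "measure_all",
    "measure_study",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """A construction line is undefined (coincident defining points)."""


@dataclass(frozen=True)
class DirectedLine:
    """An oriented line: an anchor point plus a unit direction vector."""

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"direction must be unit length, |d| = {norm}")


def _unit(dx: float, dy: float) -> tuple[float, float]:
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise DegenerateGeometryError("zero-length direction")
    return (dx / norm, dy / norm)


def signed_angle(from_dir: tuple[float, float], to_dir: tuple[float, float]) -> float:
    """Counterclockwise rotation in degrees, in (-180, 180], mapping
    ``from_dir`` onto ``to_dir``.

    Antisymmetric: ``signed_angle(a, b) == -signed_angle(b, a)`` (away from
    the 180-degree branch point).
    """
    ax, ay = from_dir
    bx, by = to_dir
    if ax == 0.0 and ay == 0.0 or bx == 0.0 and by == 0.0:
        raise DegenerateGeometryError("zero-length direction in angle")
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    deg = math.degrees(math.atan2(cross, dot))
    if deg <= -180.0:  # atan2 returns [-pi, pi]; fold -180 onto +180
        deg += 360.0
    return deg


def posterior_tangent(v: VertebraQuad) -> DirectedLine:
    """The posterior body tangent: through the posterior-inferior and
    posterior-superior corners, oriented superiorly."""
    return DirectedLine(anchor=v.pi, direction=_unit(*(v.ps - v.pi)))


def endplate_line(v: VertebraQuad, which: str) -> DirectedLine:
    """A vertebral endplate line, oriented anteriorly.

    ``which`` selects the superior endplate (through ps and as) or the
    inferior endplate (through pi and ai).
    """
    if which == "superior":
        return DirectedLine(anchor=v.ps, direction=_unit(*(v.as_ - v.ps)))
    if which == "inferior":
        return DirectedLine(anchor=v.pi, direction=_unit(*(v.ai - v.pi)))
    raise ValueError(f"which must be 'superior' or 'inferior', got {which!r}")


def compute_rra(upper: VertebraQuad, lower: VertebraQuad) -> float:
    """Relative rotation angle between adjacent vertebrae, in degrees.

    The counterclockwise angle from the lower vertebra's posterior tangent to
    the upper's; positive is extension (a lordotic segment).
    """
    return signed_angle(
        posterior_tangent(lower).direction, posterior_tangent(upper).direction
    )


def compute_ara(lset: LandmarkSet) -> float | None:
    """Absolute rotation angle C2-C7 in degrees, or None if C2/C7 absent.

    Equal (to 1e-9 degrees) to the sum of the five segmental RRAs whenever
    all are defined, because all tangent angles share one sign convention.
    """
    c2 = lset.vertebrae.get("C2")
    c7 = lset.vertebrae.get("C7")
    if c2 is None or c7 is None:
        return None
    return signed_angle(posterior_tangent(c7).direction, posterior_tangent(c2).direction)


def compute_ka(upper: VertebraQuad, lower: VertebraQuad) -> float:
    """Segmental Cobb angle across the disc, in degrees.

    The angle from the lower vertebra's superior endplate line to the upper
    vertebra's inferior endplate line (the two endplates facing the disc).
    For parallelogram-shaped bodies (no endplate wedging) this equals the
    posterior-tangent RRA at the same level.
    """
    return signed_angle(
        endplate_line(lower, "superior").direction,
        endplate_line(upper, "inferior").direction,
    )


def compute_st(upper: VertebraQuad, lower: VertebraQuad) -> float:
    """Segmental translation in mm: signed perpendicular distance of the
    upper vertebra's pi corner from the lower's posterior tangent line.

    Positive when the corner lies anterior to the line (the side reached by
    rotating the tangent direction 90 degrees clockwise — +x for a vertical
    tangent). Rigid-motion invariant, unlike a raw horizontal offset.
    """
    tangent = posterior_tangent(lower)
    tx, ty = tangent.direction
    dx, dy = upper.pi - tangent.anchor
    # anterior normal = tangent direction rotated -90 deg = (ty, -tx)
    return dx * ty - dy * tx


def compute_c1h(atlas: AtlasLandmarks | None) -> float | None:
    """Atlas plane angle vs true horizontal, degrees; None if C1 missing.

    The atlas plane line runs from the posterior laminar midpoint to the
    anterior tubercle; the angle is positive when the anterior tubercle sits
    superior to the posterior laminar midpoint. The dens landmark is stored
    for completeness but enters no measurement.
    """
    if atlas is None:
        return None
    direction = _unit(*(atlas.ant_tubercle - atlas.post_laminar_mid))
    return signed_angle((1.0, 0.0), direction)


def compute_tr(lset: LandmarkSet) -> float | None:
    """Anterior head translation in mm: x(C2.ps) - x(C7.pi); None if absent."""
    c2 = lset.vertebrae.get("C2")
    c7 = lset.vertebrae.get("C7")
    if c2 is None or c7 is None:
        return None
    return c2.ps.x - c7.pi.x


def _segment_pairs(lset: LandmarkSet):
    """Adjacent (pair_name, upper, lower) triples present in the set."""
    for upper_lvl, lower_lvl, pair in zip(CERVICAL_LEVELS, CERVICAL_LEVELS[1:], LEVEL_PAIRS):
        yield pair, lset.vertebrae.get(upper_lvl), lset.vertebrae.get(lower_lvl)


def measure_all(lset: LandmarkSet) -> MeasurementVector:
    """Compute all 18 variables for one image.

    Pure and deterministic: the same landmark set always yields bit-identical
    output (this is what makes a deterministic annotator perfectly reliable
    against itself). Variables whose prerequisite landmarks are absent or
    degenerate are reported as missing, with a warning, rather than failing
    the whole image.
    """
    values: dict[str, float | None] = {}

    def guarded(name: str, fn):
        try:
            values[name] = fn()
        except DegenerateGeometryError as exc:
            logger.warning("%s: %s undefined (%s)", lset.image_id, name, exc)
            values[name] = None

    guarded("ARA", lambda: compute_ara(lset))
    guarded("C1H", lambda: compute_c1h(lset.atlas))
    guarded("TR", lambda: compute_tr(lset))

    for pair, upper, lower in _segment_pairs(lset):
        if upper is None or lower is None:
            values[f"KA{pair}"] = values[f"RRA{pair}"] = values[f"ST{pair}"] = None
            continue
        guarded(f"KA{pair}", lambda u=upper, l=lower: compute_ka(u, l))
        guarded(f"RRA{pair}", lambda u=upper, l=lower: compute_rra(u, l))
        guarded(f"ST{pair}", lambda u=upper, l=lower: compute_st(u, l))

    return MeasurementVector(image_id=lset.image_id, values=values)


def measure_study(study: StudySet | Iterable[LandmarkSet]) -> pd.DataFrame:
    """Measure every image in a trial; wide table, one row per image."""
    return measurements_to_frame(measure_all(lset) for lset in study)
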