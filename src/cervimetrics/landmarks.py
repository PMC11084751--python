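"""Domain types, validation and file I/O for cervical-spine landmark digitization.

The digitization scheme follows the standard sagittal cervical protocol:
three points on the atlas (C1) — anterior tubercle, posterior margin of the
dens at mid-height, and the midpoint of the posterior spinal laminar line —
and four vertebral-body corners on each of C2..C7 (anterior-superior,
posterior-superior, anterior-inferior, posterior-inferior).

Coordinate frame
----------------
All geometry is carried in millimetres in a right-handed 2-D frame with
``x`` positive toward the patient's anterior and ``y`` positive superior.
Files may store coordinates in pixels together with a per-image
``mm_per_unit`` calibration factor; :func:`read_landmark_file` multiplies
coordinates into millimetres on ingest so downstream geometry never sees
raw pixel units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "CERVICAL_LEVELS",
    "CORNER_NAMES",
    "ATLAS_POINT_NAMES",
    "MEASUREMENT_VARIABLES",
    "LandmarkError",
    "ParseError",
    "ValidationError",
    "Point2D",
    "VertebraQuad",
    "AtlasLandmarks",
    "LandmarkSet",
    "StudySet",
    "MeasurementVector",
    "read_landmark_file",
    "write_landmark_file",
    "apply_rigid_transform",
    "read_measurement_csv",
    "write_measurement_csv",
]

#: Vertebral levels carrying the four-corner quad, superior to inferior.
CERVICAL_LEVELS: tuple[str, ...] = ("C2", "C3", "C4", "C5", "C6", "C7")

#: Body-corner point names: anterior/posterior x superior/inferior.
CORNER_NAMES: tuple[str, ...] = ("as", "ps", "ai", "pi")

#: Atlas (C1) point names.
ATLAS_POINT_NAMES: tuple[str, ...] = (
    "ant_tubercle",
    "dens_post_mid",
    "post_laminar_mid",
)

#: Adjacent level pairs, named by digits as in clinical reports ("23" = C2/C3).
LEVEL_PAIRS: tuple[str, ...] = ("23", "34", "45", "56", "67")

#: The 18 sagittal alignment variables, in fixed report/CSV column order.
MEASUREMENT_VARIABLES: tuple[str, ...] = (
    "ARA",
    "C1H",
    "TR",
    *(f"KA{p}" for p in LEVEL_PAIRS),
    *(f"RRA{p}" for p in LEVEL_PAIRS),
    *(f"ST{p}" for p in LEVEL_PAIRS),
)

_DEGENERACY_AREA_TOL = 1e-9  # mm^2; below this a corner quad is degenerate


class LandmarkError(ValueError):
    """Base class for landmark-schema problems."""


class ParseError(LandmarkError):
    """Raised when a landmark file does not conform to the schema."""


class ValidationError(LandmarkError):
    """Raised when parsed landmarks violate a geometric or identity invariant."""


@dataclass(frozen=True)
class Point2D:
    """A point in the sagittal plane (mm; x anterior, y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinate ({self.x}, {self.y})")

    def __sub__(self, other: "Point2D") -> tuple[float, float]:
        return (self.x - other.x, self.y - other.y)


def _shoelace_area(pts: Iterable[Point2D]) -> float:
    """Signed polygon area (shoelace formula); zero iff degenerate/collinear."""
    pts = list(pts)
    s = 0.0
    for a, b in zip(pts, pts[1:] + pts[:1]):
        s += a.x * b.y - b.x * a.y
    return 0.5 * s


@dataclass(frozen=True)
class VertebraQuad:
    """The four digitized body corners of one vertebra (C2..C7).

    ``as_`` anterior-superior, ``ps`` posterior-superior, ``ai``
    anterior-inferior, ``pi`` posterior-inferior. The trailing underscore on
    ``as_`` avoids the Python keyword; file schemas use plain ``as``.
    """

    label: str
    as_: Point2D
    ps: Point2D
    ai: Point2D
    pi: Point2D

    def __post_init__(self) -> None:
        if self.label not in CERVICAL_LEVELS:
            raise ValidationError(f"vertebra label {self.label!r} not in C2..C7")
        if self.ps == self.pi:
            raise ValidationError(
                f"{self.label}: ps == pi, posterior tangent undefined"
            )
        if self.as_ == self.ai:
            raise ValidationError(f"{self.label}: as == ai, anterior margin undefined")
        area = _shoelace_area([self.as_, self.ps, self.pi, self.ai])
        if abs(area) <= _DEGENERACY_AREA_TOL:
            raise ValidationError(
                f"{self.label}: corner quad degenerate (|signed area| = {abs(area):g} mm^2)"
            )

    def corner(self, name: str) -> Point2D:
        return getattr(self, "as_" if name == "as" else name)


@dataclass(frozen=True)
class AtlasLandmarks:
    """The three C1 points: anterior tubercle, posterior dens midpoint and
    posterior laminar-line midpoint."""

    ant_tubercle: Point2D
    dens_post_mid: Point2D
    post_laminar_mid: Point2D

    def __post_init__(self) -> None:
        if self.ant_tubercle == self.post_laminar_mid:
            raise ValidationError(
                "C1: ant_tubercle == post_laminar_mid, atlas plane line undefined"
            )


@dataclass(frozen=True)
class LandmarkSet:
    """All digitized points of one lateral cervical image, in millimetres.

    ``mm_per_unit`` records the calibration factor the source file declared;
    the stored coordinates have already been multiplied into mm. The atlas
    block is optional: without it the atlas plane angle (C1H) is simply
    unmeasurable while the other 17 variables remain computable.
    """

    image_id: str
    vertebrae: Mapping[str, VertebraQuad]
    atlas: AtlasLandmarks | None = None
    mm_per_unit: float = 1.0
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.mm_per_unit > 0 and math.isfinite(self.mm_per_unit)):
            raise ValidationError(
                f"{self.image_id}: mm_per_unit must be positive, got {self.mm_per_unit}"
            )
        for level, quad in self.vertebrae.items():
            if level not in CERVICAL_LEVELS:
                raise ValidationError(f"{self.image_id}: unknown level {level!r}")
            if quad.label != level:
                raise ValidationError(
                    f"{self.image_id}: quad labelled {quad.label!r} stored under {level!r}"
                )
        object.__setattr__(self, "vertebrae", dict(self.vertebrae))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def complete(self) -> bool:
        """True iff all six of C2..C7 are present (C1 not required)."""
        return all(lvl in self.vertebrae for lvl in CERVICAL_LEVELS)


@dataclass
class StudySet:
    """One digitization trial: an ordered collection of LandmarkSets.

    ``rater_id`` identifies the annotator ("US1", "US2" for the human trials,
    "CV" for the deterministic computer annotator)."""

    trial_id: str
    rater_id: str
    sets: dict[str, LandmarkSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id, lset in self.sets.items():
            if lset.image_id != image_id:
                raise ValidationError(
                    f"set keyed {image_id!r} has image_id {lset.image_id!r}"
                )

    def add(self, lset: LandmarkSet) -> None:
        if lset.image_id in self.sets:
            raise ValidationError(f"duplicate image_id {lset.image_id!r}")
        self.sets[lset.image_id] = lset

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass(frozen=True)
class MeasurementVector:
    """The 18 named sagittal alignment variables for one image.

    Angles in degrees, translations in mm; ``None`` marks a variable whose
    prerequisite landmarks were absent or degenerate. When the global curve
    (ARA) and all five segmental rotations (RRA) are present, ARA equals
    their sum exactly (shared-sign telescoping); construction enforces this
    to 1e-9 degrees.
    """

    image_id: str
    values: Mapping[str, float | None]

    def __post_init__(self) -> None:
        extra = set(self.values) - set(MEASUREMENT_VARIABLES)
        missing = set(MEASUREMENT_VARIABLES) - set(self.values)
        if extra or missing:
            raise ValidationError(
                f"{self.image_id}: expected exactly the 18 named variables; "
                f"extra={sorted(extra)} missing={sorted(missing)}"
            )
        for name, v in self.values.items():
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"{self.image_id}: {name} is non-finite")
        rras = [self.values[f"RRA{p}"] for p in LEVEL_PAIRS]
        ara = self.values["ARA"]
        if ara is not None and all(v is not None for v in rras):
            if abs(ara - sum(rras)) > 1e-9:
                raise ValidationError(
                    f"{self.image_id}: ARA {ara} != sum of RRA {sum(rras)}"
                )
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float | None:
        return self.values[name]

    def to_dict(self) -> dict[str, float | None]:
        return {name: self.values[name] for name in MEASUREMENT_VARIABLES}


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _point_from_xy(raw, *, image_id: str, where: str) -> Point2D:
    try:
        x, y = float(raw[0]), float(raw[1])
    except (TypeError, ValueError, IndexError, KeyError) as exc:
        raise ParseError(f"{image_id}: bad coordinate pair at {where}: {raw!r}") from exc
    return Point2D(x, y)


def _scale_point(p: Point2D, s: float) -> Point2D:
    return Point2D(p.x * s, p.y * s)


def _image_from_json(rec: dict) -> LandmarkSet:
    try:
        image_id = str(rec["image_id"])
    except KeyError as exc:
        raise ParseError("image record missing 'image_id'") from exc
    mm = float(rec.get("mm_per_unit", 1.0))
    if not mm > 0:
        raise ValidationError(f"{image_id}: mm_per_unit must be positive, got {mm}")

    atlas = None
    if "C1" in rec and rec["C1"] is not None:
        c1 = rec["C1"]
        pts = {}
        for name in ATLAS_POINT_NAMES:
            if name not in c1:
                raise ParseError(f"{image_id}: C1 block missing point {name!r}")
            pts[name] = _scale_point(
                _point_from_xy(c1[name], image_id=image_id, where=f"C1.{name}"), mm
            )
        atlas = AtlasLandmarks(**pts)

    vertebrae = {}
    for level in CERVICAL_LEVELS:
        if level not in rec or rec[level] is None:
            continue
        block = rec[level]
        corners = {}
        for name in CORNER_NAMES:
            if name not in block:
                raise ParseError(f"{image_id}: {level} block missing corner {name!r}")
            corners["as_" if name == "as" else name] = _scale_point(
                _point_from_xy(block[name], image_id=image_id, where=f"{level}.{name}"),
                mm,
            )
        vertebrae[level] = VertebraQuad(label=level, **corners)

    metadata = {str(k): str(v) for k, v in (rec.get("metadata") or {}).items()}
    return LandmarkSet(
        image_id=image_id,
        vertebrae=vertebrae,
        atlas=atlas,
        mm_per_unit=mm,
        metadata=metadata,
    )


def _study_from_json(obj: dict) -> StudySet:
    if not isinstance(obj, dict) or "images" not in obj:
        raise ParseError("landmark JSON must be an object with an 'images' array")
    study = StudySet(
        trial_id=str(obj.get("trial_id", "")), rater_id=str(obj.get("rater_id", ""))
    )
    for rec in obj["images"]:
        study.add(_image_from_json(rec))
    return study


def _study_from_csv(frame: pd.DataFrame) -> StudySet:
    required = {"image_id", "vertebra", "point", "x", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"landmark CSV missing columns: {sorted(missing)}")
    if "mm_per_unit" not in frame.columns:
        frame = frame.assign(mm_per_unit=1.0)

    study = StudySet(trial_id="", rater_id="")
    for image_id, img in frame.groupby("image_id", sort=False):
        mm_vals = img["mm_per_unit"].astype(float).unique()
        if len(mm_vals) != 1:
            raise ParseError(f"{image_id}: inconsistent mm_per_unit values {mm_vals}")
        mm = float(mm_vals[0])
        if not mm > 0:
            raise ValidationError(f"{image_id}: mm_per_unit must be positive, got {mm}")

        dupes = img.duplicated(subset=["vertebra", "point"])
        if dupes.any():
            bad = img.loc[dupes, ["vertebra", "point"]].iloc[0]
            raise ParseError(
                f"{image_id}: duplicate landmark ({bad['vertebra']}, {bad['point']})"
            )

        pts: dict[tuple[str, str], Point2D] = {}
        for row in img.itertuples(index=False):
            p = _point_from_xy(
                (row.x, row.y), image_id=str(image_id), where=f"{row.vertebra}.{row.point}"
            )
            pts[(str(row.vertebra), str(row.point))] = _scale_point(p, mm)

        atlas = None
        c1_pts = {name: pts.get(("C1", name)) for name in ATLAS_POINT_NAMES}
        if any(v is not None for v in c1_pts.values()):
            if any(v is None for v in c1_pts.values()):
                raise ParseError(f"{image_id}: incomplete C1 block")
            atlas = AtlasLandmarks(**c1_pts)  # type: ignore[arg-type]

        vertebrae = {}
        for level in CERVICAL_LEVELS:
            corners = {name: pts.get((level, name)) for name in CORNER_NAMES}
            if all(v is None for v in corners.values()):
                continue
            if any(v is None for v in corners.values()):
                absent = [n for n, v in corners.items() if v is None]
                raise ParseError(f"{image_id}: {level} missing corners {absent}")
            vertebrae[level] = VertebraQuad(
                label=level,
                **{("as_" if n == "as" else n): p for n, p in corners.items()},
            )
        study.add(
            LandmarkSet(
                image_id=str(image_id),
                vertebrae=vertebrae,
                atlas=atlas,
                mm_per_unit=mm,
            )
        )
    return study


def read_landmark_file(source: str | Path | IO[str], format: str | None = None) -> StudySet:
    """Read a landmark file (JSON or long-format CSV) into a validated StudySet.

    Coordinates are multiplied by the file's ``mm_per_unit`` on ingest, so the
    returned geometry is always in millimetres. ``format`` defaults to the
    file extension.
    """
    if hasattr(source, "read"):
        text = source.read()
        fmt = format or "json"
    else:
        path = Path(source)
        text = path.read_text()
        fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")

    if fmt == "json":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc}") from exc
        return _study_from_json(obj)
    if fmt == "csv":
        import io

        return _study_from_csv(pd.read_csv(io.StringIO(text)))
    raise ValueError(f"unknown landmark format {fmt!r}")


def _point_to_file_units(p: Point2D, mm: float) -> list[float]:
    return [p.x / mm, p.y / mm]


def write_landmark_file(study: StudySet, dest: str | Path, format: str | None = None) -> None:
    """Write a StudySet to JSON or long CSV.

    Coordinates are divided back by each image's ``mm_per_unit`` so the file
    round-trips: ``read_landmark_file(write_landmark_file(s))`` reproduces
    the in-memory mm coordinates to better than 1e-9 mm.
    """
    path = Path(dest)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")

    if fmt == "json":
        images = []
        for lset in study:
            rec: dict = {
                "image_id": lset.image_id,
                "mm_per_unit": lset.mm_per_unit,
                "metadata": dict(lset.metadata),
            }
            if lset.atlas is not None:
                rec["C1"] = {
                    name: _point_to_file_units(getattr(lset.atlas, name), lset.mm_per_unit)
                    for name in ATLAS_POINT_NAMES
                }
            for level, quad in lset.vertebrae.items():
                rec[level] = {
                    name: _point_to_file_units(quad.corner(name), lset.mm_per_unit)
                    for name in CORNER_NAMES
                }
            images.append(rec)
        obj = {"trial_id": study.trial_id, "rater_id": study.rater_id, "images": images}
        path.write_text(json.dumps(obj, indent=1) + "\n")
        return

    if fmt == "csv":
        rows = []
        for lset in study:
            mm = lset.mm_per_unit
            if lset.atlas is not None:
                for name in ATLAS_POINT_NAMES:
                    p = getattr(lset.atlas, name)
                    rows.append((lset.image_id, "C1", name, p.x / mm, p.y / mm, mm))
            for level, quad in lset.vertebrae.items():
                for name in CORNER_NAMES:
                    p = quad.corner(name)
                    rows.append((lset.image_id, level, name, p.x / mm, p.y / mm, mm))
        frame = pd.DataFrame(
            rows, columns=["image_id", "vertebra", "point", "x", "y", "mm_per_unit"]
        )
        frame.to_csv(path, index=False)
        return

    raise ValueError(f"unknown landmark format {fmt!r}")


# ---------------------------------------------------------------------------
# Geometric transforms (test harness for invariance properties)
# ---------------------------------------------------------------------------

def _transform_point(
    p: Point2D, cos_t: float, sin_t: float, tx: float, ty: float, s: float
) -> Point2D:
    return Point2D(
        s * (cos_t * p.x - sin_t * p.y) + tx,
        s * (sin_t * p.x + cos_t * p.y) + ty,
    )


def apply_rigid_transform(
    lset: LandmarkSet,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> LandmarkSet:
    """Map every point to ``scale * R(rotation) * p + translation``.

    Rotation is counterclockwise in degrees about the origin; labels,
    calibration and metadata are preserved.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    t = math.radians(rotation_deg)
    c, s_ = math.cos(t), math.sin(t)
    tx, ty = translation

    def tp(p: Point2D) -> Point2D:
        return _transform_point(p, c, s_, tx, ty, scale)

    atlas = None
    if lset.atlas is not None:
        atlas = AtlasLandmarks(
            ant_tubercle=tp(lset.atlas.ant_tubercle),
            dens_post_mid=tp(lset.atlas.dens_post_mid),
            post_laminar_mid=tp(lset.atlas.post_laminar_mid),
        )
    vertebrae = {
        level: VertebraQuad(
            label=level, as_=tp(q.as_), ps=tp(q.ps), ai=tp(q.ai), pi=tp(q.pi)
        )
        for level, q in lset.vertebrae.items()
    }
    return replace(lset, vertebrae=vertebrae, atlas=atlas)


# ---------------------------------------------------------------------------
# Measurement tables (wide CSV)
# ---------------------------------------------------------------------------

def measurements_to_frame(vectors: Iterable[MeasurementVector]) -> pd.DataFrame:
    """Stack MeasurementVectors into a wide table indexed by image_id."""
    rows = {v.image_id: v.to_dict() for v in vectors}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASUREMENT_VARIABLES))
    frame.index.name = "image_id"
    return frame.astype(float)


def write_measurement_csv(frame: pd.DataFrame, dest: str | Path) -> None:
    """Write a wide measurement table; missing values become empty fields."""
    frame = frame.reindex(columns=list(MEASUREMENT_VARIABLES))
    frame.to_csv(dest, index=True, na_rep="")


def read_measurement_csv(source: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(source, index_col="image_id")
    missing = set(MEASUREMENT_VARIABLES) - set(frame.columns)
    if missing:
        raise ParseError(f"measurement CSV missing columns: {sorted(missing)}")
    return frame[list(MEASUREMENT_VARIABLES)].astype(float)
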