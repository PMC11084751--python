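"""Synthetic cervical-spine landmark generator with known ground truth.

Builds parametric sagittal spines whose alignment variables are exact by
construction, then simulates annotator behaviour on them: two independent
noisy digitization trials for a human rater and a deterministic
computer-vision annotator whose output never varies across repeats.

Construction
------------
The spine is parametrized directly by posterior-tangent direction angles
rather than by fitting an arc: the C7 tangent angle is the base tilt, and
each level above adds its configured fraction of the total curve, so the
global angle (ARA) and every segmental rotation (RRA) are exact identities
of the construction, not approximations. Vertebral bodies are stacked
bottom-up from the C7 posterior-inferior corner at the origin; disc gaps
separate adjacent bodies along the mean tangent direction, optional
segmental translations (listhesis) shift a body along the anterior normal,
and optional endplate wedges tilt the anterior corners about the posterior
ones — these two play the role of a cohort's degenerative changes. An atlas
plane line of fixed span sits above C2 at a configured angle to the
horizontal.

Annotator noise is isotropic Gaussian per landmark with a single sigma (a
per-landmark sigma map can be supplied, since endplate corners are the less
reliable points on degenerated spines). A master seed derives independent,
reproducible substreams per (rater, trial, image); sigma = 0 reproduces the
ground truth bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .landmarks import (
    ATLAS_POINT_NAMES,
    CERVICAL_LEVELS,
    CORNER_NAMES,
    LEVEL_PAIRS,
    MEASUREMENT_VARIABLES,
    AtlasLandmarks,
    LandmarkSet,
    Point2D,
    StudySet,
    VertebraQuad,
    apply_rigid_transform,
    write_landmark_file,
)

__all__ = [
    "GeneratorConfig",
    "NoiseModel",
    "TruthRecord",
    "generate_spine",
    "generate_cohort",
    "perturb",
    "simulate_study",
    "load_config",
    "save_config",
]

_RATER_STREAM_IDS = {"US1": 1, "US2": 2, "CV": 3}


@dataclass
class GeneratorConfig:
    """Parametric spine geometry and cohort distributions.

    Angles in degrees, lengths in mm. Defaults describe a plausible adult
    cervical cohort: total lordosis (C2-C7 posterior-tangent angle) drawn
    from Normal(20, 10), shared equally across the five motion segments,
    vertebral bodies 11 mm tall (18 mm for the taller C2) and 16 mm deep
    with 5 mm disc spaces.
    """

    n_images: int = 254
    seed: int = 0
    # global curve: ARA ~ Normal(ara_mean, ara_sd)
    ara_mean: float = 20.0
    ara_sd: float = 10.0
    # fraction of the curve carried by each segment (C2/3 .. C6/7)
    segment_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    # optional Dirichlet spread of per-image weights about segment_weights;
    # None = every image uses the configured weights exactly
    weight_concentration: float | None = None
    # C7 posterior-tangent tilt ~ Normal(base_tilt_mean, base_tilt_sd)
    base_tilt_mean: float = 0.0
    base_tilt_sd: float = 5.0
    body_heights: Mapping[str, float] = field(
        default_factory=lambda: {"C2": 18.0, "C3": 11.0, "C4": 11.0, "C5": 11.0, "C6": 11.0, "C7": 11.0}
    )
    body_depths: Mapping[str, float] = field(
        default_factory=lambda: {lvl: 16.0 for lvl in CERVICAL_LEVELS}
    )
    disc_gap: float = 5.0
    # fixed anterior(+)/posterior(-) listhesis per level pair, mm
    translations: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in LEVEL_PAIRS}
    )
    translation_sd: float = 0.0
    # fixed endplate wedge per (level, endplate), deg; positive tilts the
    # anterior corner superiorly about the posterior corner
    wedges: Mapping[str, float] = field(default_factory=dict)
    wedge_sd: float = 0.0
    # atlas plane line
    include_atlas: bool = True
    atlas_angle_mean: float = 18.0
    atlas_angle_sd: float = 6.0
    atlas_span: float = 45.0
    atlas_offset: float = 12.0
    # global pose per image
    global_rotation_sd: float = 2.0
    global_translation_sd: float = 20.0
    global_scale: float = 1.0
    mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.segment_weights, dtype=float)
        if w.size != 5 or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"segment_weights must be 5 fractions summing to 1, got {self.segment_weights}"
            )
        for name, m in (("body_heights", self.body_heights), ("body_depths", self.body_depths)):
            for lvl in CERVICAL_LEVELS:
                if not m.get(lvl, 0) > 0:
                    raise ValueError(f"{name}[{lvl}] must be positive")
        if not self.disc_gap > 0:
            raise ValueError("disc_gap must be positive")
        if not self.global_scale > 0:
            raise ValueError("global_scale must be positive")
        if not self.mm_per_unit > 0:
            raise ValueError("mm_per_unit must be positive")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass
class NoiseModel:
    """Annotator landmark noise: isotropic Gaussian displacement in mm.

    ``sigma_landmark`` applies to the human trials (US1, US2).
    ``cv_sigma`` is the deterministic annotator's fixed deviation from
    truth: drawn once per image and replicated, so re-measuring the CV trial
    is always an identity experiment. ``per_landmark_sigma`` optionally
    overrides sigma for named points (e.g. {"ai": 0.3, "as": 0.3}).
    """

    sigma_landmark: float = 0.16
    cv_sigma: float = 0.0
    per_landmark_sigma: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_landmark < 0 or self.cv_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if any(v < 0 for v in self.per_landmark_sigma.values()):
            raise ValueError("per-landmark sigmas must be >= 0")

    def sigma_for(self, point_name: str, base: float) -> float:
        return float(self.per_landmark_sigma.get(point_name, base))


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth values of the 18 variables implied by the construction."""

    image_id: str
    values: Mapping[str, float]

    def to_dict(self) -> dict[str, float]:
        return {name: float(self.values[name]) for name in MEASUREMENT_VARIABLES}


def _u(psi_deg: float) -> np.ndarray:
    """Posterior-tangent direction (superior) at tangent angle psi.

    psi is the counterclockwise angle from the +y axis; psi > 0 tips the
    superior end posteriorly (extension)."""
    r = math.radians(psi_deg)
    return np.array([-math.sin(r), math.cos(r)])


def _n(psi_deg: float) -> np.ndarray:
    """Anterior normal of the tangent at angle psi (tangent rotated -90 deg)."""
    r = math.radians(psi_deg)
    return np.array([math.cos(r), math.sin(r)])


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_spine(
    cfg: GeneratorConfig,
    image_id: str = "img",
    *,
    ara: float | None = None,
    base_tilt: float | None = None,
    weights: np.ndarray | None = None,
    translations: Mapping[str, float] | None = None,
    wedges: Mapping[str, float] | None = None,
    atlas_angle: float | None = None,
    global_rotation: float = 0.0,
    global_translation: tuple[float, float] = (0.0, 0.0),
) -> tuple[LandmarkSet, TruthRecord]:
    """Build one spine from explicit per-image parameters.

    Parameters left as None fall back to the config's deterministic values
    (means for the distributions). Cohort sampling lives in
    :func:`generate_cohort`; this function is deterministic.
    """
    alpha = cfg.ara_mean if ara is None else ara
    psi_c7 = cfg.base_tilt_mean if base_tilt is None else base_tilt
    w = np.asarray(cfg.segment_weights if weights is None else weights, dtype=float)
    s_by_pair = dict(cfg.translations) if translations is None else dict(translations)
    wedge_by_key = dict(cfg.wedges) if wedges is None else dict(wedges)
    eta = cfg.atlas_angle_mean if atlas_angle is None else atlas_angle

    # tangent angles bottom-up: psi[C7]=base tilt, each segment adds its share
    levels_bottom_up = list(reversed(CERVICAL_LEVELS))  # C7..C2
    pairs_bottom_up = list(reversed(LEVEL_PAIRS))  # 67..23
    psi = {"C7": psi_c7}
    for pair, lower, upper in zip(pairs_bottom_up, levels_bottom_up, levels_bottom_up[1:]):
        share = alpha * w[LEVEL_PAIRS.index(pair)]
        psi[upper] = psi[lower] + share

    def wedge(level: str, which: str) -> float:
        return float(wedge_by_key.get(f"{level}_{which}", 0.0))

    quads: dict[str, VertebraQuad] = {}
    pi_pos = np.zeros(2)  # C7 posterior-inferior corner at the origin
    truth: dict[str, float] = {}
    for i, level in enumerate(levels_bottom_up):
        h = float(cfg.body_heights[level])
        d = float(cfg.body_depths[level])
        p = psi[level]
        ps_pos = pi_pos + h * _u(p)
        ai_pos = pi_pos + d * _rot(_n(p), wedge(level, "inf"))
        as_pos = ps_pos + d * _rot(_n(p), wedge(level, "sup"))
        quads[level] = VertebraQuad(
            label=level,
            as_=Point2D(*as_pos),
            ps=Point2D(*ps_pos),
            ai=Point2D(*ai_pos),
            pi=Point2D(*pi_pos),
        )
        if level != "C2":
            upper = levels_bottom_up[i + 1]
            pair = pairs_bottom_up[i]
            s_mm = float(s_by_pair.get(pair, 0.0))
            psi_mid = 0.5 * (p + psi[upper])
            pi_pos = ps_pos + cfg.disc_gap * _u(psi_mid) + s_mm * _n(psi_mid)
            # exact ST implied by the construction (perpendicular offset of
            # the upper pi from the lower posterior tangent line)
            delta = psi[upper] - p
            truth[f"ST{pair}"] = -cfg.disc_gap * math.sin(math.radians(delta / 2.0)) + s_mm * math.cos(
                math.radians(delta / 2.0)
            )

    atlas = None
    if cfg.include_atlas:
        c2 = quads["C2"]
        center = 0.5 * (
            np.array([c2.ps.x, c2.ps.y]) + np.array([c2.as_.x, c2.as_.y])
        ) + cfg.atlas_offset * _u(psi["C2"])
        half = 0.5 * cfg.atlas_span * np.array(
            [math.cos(math.radians(eta)), math.sin(math.radians(eta))]
        )
        atlas = AtlasLandmarks(
            ant_tubercle=Point2D(*(center + half)),
            dens_post_mid=Point2D(*(center + 0.5 * half)),
            post_laminar_mid=Point2D(*(center - half)),
        )

    lset = LandmarkSet(
        image_id=image_id,
        vertebrae=quads,
        atlas=atlas,
        mm_per_unit=cfg.mm_per_unit,
    )
    scale = cfg.global_scale
    if global_rotation != 0.0 or global_translation != (0.0, 0.0) or scale != 1.0:
        lset = apply_rigid_transform(
            lset, rotation_deg=global_rotation, translation=global_translation, scale=scale
        )

    # rotation-invariant truths, exact by construction
    truth["ARA"] = alpha
    for pair in LEVEL_PAIRS:
        truth[f"RRA{pair}"] = alpha * w[LEVEL_PAIRS.index(pair)]
    for pair, upper, lower in zip(LEVEL_PAIRS, CERVICAL_LEVELS, CERVICAL_LEVELS[1:]):
        truth[f"KA{pair}"] = truth[f"RRA{pair}"] + wedge(upper, "inf") - wedge(lower, "sup")
        truth[f"ST{pair}"] = truth[f"ST{pair}"] * scale
    truth["C1H"] = (eta + global_rotation) if cfg.include_atlas else float("nan")
    # TR is frame-dependent (horizontal offset), so read it from the final pose
    truth["TR"] = lset.vertebrae["C2"].ps.x - lset.vertebrae["C7"].pi.x
    return lset, TruthRecord(image_id=image_id, values=truth)


def _image_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream, index])


def generate_cohort(cfg: GeneratorConfig) -> tuple[StudySet, pd.DataFrame]:
    """Sample cfg.n_images spines; returns the truth trial and truth table.

    All per-image parameters are drawn from labelled substreams of the
    master seed, so a given (config, seed) reproduces the cohort exactly.
    """
    study = StudySet(trial_id="truth", rater_id="truth")
    records = []
    for i in range(cfg.n_images):
        rng = _image_rng(cfg.seed, 0, i)
        image_id = f"img{i:04d}"
        weights = np.asarray(cfg.segment_weights, dtype=float)
        if cfg.weight_concentration is not None:
            weights = rng.dirichlet(weights * cfg.weight_concentration)
        translations = {
            p: float(cfg.translations.get(p, 0.0) + cfg.translation_sd * rng.standard_normal())
            for p in LEVEL_PAIRS
        }
        wedges = dict(cfg.wedges)
        if cfg.wedge_sd > 0:
            for lvl in CERVICAL_LEVELS:
                for which in ("sup", "inf"):
                    wedges[f"{lvl}_{which}"] = float(
                        wedges.get(f"{lvl}_{which}", 0.0) + cfg.wedge_sd * rng.standard_normal()
                    )
        lset, truth = generate_spine(
            cfg,
            image_id=image_id,
            ara=float(rng.normal(cfg.ara_mean, cfg.ara_sd)),
            base_tilt=float(rng.normal(cfg.base_tilt_mean, cfg.base_tilt_sd)),
            weights=weights,
            translations=translations,
            wedges=wedges,
            atlas_angle=float(rng.normal(cfg.atlas_angle_mean, cfg.atlas_angle_sd)),
            global_rotation=float(rng.normal(0.0, cfg.global_rotation_sd)),
            global_translation=(
                float(rng.normal(0.0, cfg.global_translation_sd)),
                float(rng.normal(0.0, cfg.global_translation_sd)),
            ),
        )
        study.add(lset)
        records.append({"image_id": image_id, **truth.to_dict()})
    table = pd.DataFrame.from_records(records).set_index("image_id")
    return study, table[list(MEASUREMENT_VARIABLES)]


def perturb(
    lset: LandmarkSet, noise: NoiseModel, rng: np.random.Generator, sigma: float | None = None
) -> LandmarkSet:
    """Displace every landmark by independent Normal(0, sigma^2) in x and y.

    image_id, calibration and metadata are preserved; sigma = 0 returns an
    identical set.
    """
    base = noise.sigma_landmark if sigma is None else sigma

    def jitter(p: Point2D, name: str) -> Point2D:
        s = noise.sigma_for(name, base)
        dx, dy = rng.normal(0.0, 1.0, size=2)
        return Point2D(p.x + s * dx, p.y + s * dy) if s > 0 else Point2D(p.x + 0 * dx, p.y + 0 * dy)

    atlas = None
    if lset.atlas is not None:
        atlas = AtlasLandmarks(
            **{name: jitter(getattr(lset.atlas, name), name) for name in ATLAS_POINT_NAMES}
        )
    vertebrae = {
        level: VertebraQuad(
            label=level,
            **{
                ("as_" if n_ == "as" else n_): jitter(q.corner(n_), n_)
                for n_ in CORNER_NAMES
            },
        )
        for level, q in lset.vertebrae.items()
    }
    return LandmarkSet(
        image_id=lset.image_id,
        vertebrae=vertebrae,
        atlas=atlas,
        mm_per_unit=lset.mm_per_unit,
        metadata=lset.metadata,
    )


def simulate_study(
    cfg: GeneratorConfig, noise: NoiseModel, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, StudySet]]:
    """Run the full repeated-measures design on a synthetic cohort.

    Returns the truth table and three trials: US1 and US2 are independent
    noisy digitizations by the simulated human rater; CV is the
    deterministic annotator — one fixed perturbation (the truth itself when
    cv_sigma = 0), identical on every re-measurement. With ``out_dir``,
    writes one landmark JSON per trial, the truth CSV and a manifest.
    """
    truth_study, truth_table = generate_cohort(cfg)

    trials: dict[str, StudySet] = {}
    for rater in ("US1", "US2", "CV"):
        stream = _RATER_STREAM_IDS[rater]
        sigma = noise.cv_sigma if rater == "CV" else noise.sigma_landmark
        study = StudySet(trial_id=rater, rater_id=rater)
        for i, lset in enumerate(truth_study):
            rng = _image_rng(cfg.seed, stream, i)
            study.add(perturb(lset, noise, rng, sigma=sigma))
        trials[rater] = study

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rater, study in trials.items():
            write_landmark_file(study, out / f"landmarks_{rater}.json")
        truth_table.to_csv(out / "truth.csv")
        manifest = {
            "seed": cfg.seed,
            "n_images": cfg.n_images,
            "config_sha256": config_hash(cfg, noise),
            "outputs": [f"landmarks_{r}.json" for r in trials] + ["truth.csv"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return truth_table, trials


# ---------------------------------------------------------------------------
# YAML config plumbing
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def config_hash(cfg: GeneratorConfig, noise: NoiseModel) -> str:
    blob = json.dumps(
        {"generator": _to_plain(asdict(cfg)), "noise": _to_plain(asdict(noise))},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def save_config(cfg: GeneratorConfig, noise: NoiseModel, path: str | Path) -> None:
    doc = {"generator": _to_plain(asdict(cfg)), "noise": _to_plain(asdict(noise))}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[GeneratorConfig, NoiseModel]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    gen = dict(doc.get("generator", {}))
    if "segment_weights" in gen:
        gen["segment_weights"] = tuple(float(v) for v in gen["segment_weights"])
    try:
        cfg = GeneratorConfig(**gen)
        noise = NoiseModel(**dict(doc.get("noise", {})))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid simulation config: {exc}") from exc
    return cfg, noise
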