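import numpy as np
import pytest

from cervimetrics import (
    CERVICAL_LEVELS,
    LEVEL_PAIRS,
    GeneratorConfig,
    NoiseModel,
    generate_spine,
    perturb,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_landmark_set(rng, image_id="rand", with_atlas=True, jitter=0.4):
    """A random anatomically-plausible but irregular landmark set.

    Draws a spine with random curve, segment shares, listhesis, endplate
    wedging and global pose, then jitters every landmark so the corner quads
    are generic (non-parallelogram, non-symmetric) while staying far from
    degeneracy.
    """
    cfg = GeneratorConfig(n_images=1, seed=0, include_atlas=with_atlas)
    lset, _ = generate_spine(
        cfg,
        image_id=image_id,
        ara=float(rng.normal(20, 10)),
        base_tilt=float(rng.normal(0, 5)),
        weights=rng.dirichlet(np.full(5, 30.0)),
        translations={p: float(rng.normal(0, 1)) for p in LEVEL_PAIRS},
        wedges={
            f"{lvl}_{which}": float(rng.normal(0, 2))
            for lvl in CERVICAL_LEVELS
            for which in ("sup", "inf")
        },
        atlas_angle=float(rng.normal(18, 6)),
        global_rotation=float(rng.normal(0, 10)),
        global_translation=(float(rng.normal(0, 30)), float(rng.normal(0, 30))),
    )
    if jitter > 0:
        lset = perturb(lset, NoiseModel(sigma_landmark=jitter), rng)
    return lset
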