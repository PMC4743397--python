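import numpy as np
import pytest

from cytoblock.config import RunConfig
from cytoblock.image_prep import ColorPlanes, to_color_planes
from cytoblock.pipeline import run_synthetic_experiment
from cytoblock.synthetic import SyntheticSpec, generate_image


@pytest.fixture(scope="session")
def experiment():
    """One full synthetic screen: 14 training + 12 test slides, tenfold-CV
    grid search (0.5 log-step test grid), prediction and scoring."""
    return run_synthetic_experiment(RunConfig(seed=0, grid_step=0.5))


@pytest.fixture(scope="session")
def synthetic_image():
    """A single seeded synthetic slide with ground truth."""
    return generate_image(SyntheticSpec(seed=11))


def _block_of(image, truth, phenotype):
    rows, cols = truth.phenotypes.shape
    bs = 100
    for i in range(rows):
        for j in range(cols):
            if truth.phenotypes[i, j] == phenotype:
                return image.pixels[i * bs : (i + 1) * bs, j * bs : (j + 1) * bs]
    raise LookupError(f"no {phenotype} block in fixture image")


@pytest.fixture(scope="session")
def normal_planes(synthetic_image):
    image, truth = synthetic_image
    return to_color_planes(_block_of(image, truth, "normal"))


@pytest.fixture(scope="session")
def suspicious_planes(synthetic_image):
    image, truth = synthetic_image
    return to_color_planes(_block_of(image, truth, "suspicious"))


@pytest.fixture(scope="session")
def background_planes(synthetic_image):
    image, truth = synthetic_image
    return to_color_planes(_block_of(image, truth, "background"))


@pytest.fixture(scope="session")
def feature_groups(synthetic_image):
    """11-feature matrices of the fixture image's blocks, keyed by class
    ('normal' = all non-suspicious cell-bearing phenotypes)."""
    from cytoblock.features import assemble
    from cytoblock.image_prep import tile

    image, truth = synthetic_image
    groups = {"normal": [], "suspicious": []}
    for (i, j), block in tile(image):
        phen = truth.phenotypes[i, j]
        if phen == "background":
            continue
        key = "suspicious" if phen == "suspicious" else "normal"
        groups[key].append(assemble(to_color_planes(block), check_background=False).values)
    return {k: np.array(v) for k, v in groups.items()}


def make_planes(gray, r_channel=None, intensity=None):
    """ColorPlanes straight from arrays (no median filtering), for tests
    that need exact control over plane values."""
    gray = np.asarray(gray, dtype=float)
    return ColorPlanes(
        r_channel=gray.copy() if r_channel is None else np.asarray(r_channel, dtype=float),
        gray=gray,
        intensity=gray / 255.0 if intensity is None else np.asarray(intensity, dtype=float),
    )
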