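import numpy as np
import pytest

import wingmorph as wm


def random_shape(rng, k=10):
    """A generic non-degenerate landmark configuration."""
    return rng.normal(size=(k, 2))


def similarity_transform(rng, shape, scale_range=(0.5, 2.0),
                         translation_range=5.0):
    theta = rng.uniform(-np.pi, np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return (rng.uniform(*scale_range) * shape @ rot.T
            + rng.uniform(-translation_range, translation_range, 2))


@pytest.fixture(scope="session")
def study_dataset():
    """One synthetic dataset with the full study design (12 species, n=312)."""
    return wm.generate(wm.make_default_spec(11))


@pytest.fixture(scope="session")
def study_proc(study_dataset):
    return wm.generalized_procrustes(study_dataset)


@pytest.fixture()
def two_group_dataset():
    """Small two-species dataset with clear but imperfect separation."""
    spec = wm.GeneratorSpec(
        taxa=[wm.TaxonSpec("G", "S", "sp1", 20), wm.TaxonSpec("G", "S", "sp2", 20)],
        genus_offset_sd=0.0, subgenus_offset_sd=0.0, species_offset_sd=0.02,
        within_species_sd=0.01, allometry_fraction=0.0, seed=3,
    )
    return wm.generate(spec)
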