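"""Shared fixtures: synthetic cohorts at the sizes the suite needs."""

import numpy as np
import pytest

from nodulefuse.cnn import ArchitectureSpec
from nodulefuse.data import BIOMARKER_NAMES, NoduleRecord
from nodulefuse.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate-noise cohort at the generator's default study conditions."""
    return generate_cohort(GeneratorConfig(n_nodules=300, seed=11))


@pytest.fixture(scope="session")
def separable_cohort():
    """High-effect, low-noise cohort with latent ground truth attached."""
    config = GeneratorConfig(n_nodules=600, biomarker_effect=2.0, noise_sd=0.3, seed=7)
    records, latents = generate_cohort(config, return_latent=True)
    return config, records, latents


@pytest.fixture(scope="session")
def big_cohort():
    """Archive-sized cohort (4505 annotations) for count/fraction checks."""
    return generate_cohort(GeneratorConfig(n_nodules=4505, seed=0))


@pytest.fixture(scope="session")
def narrow_arch():
    """A narrow CNN variant for fast training tests (feature width kept 64)."""
    return ArchitectureSpec().scaled(8)


def make_record(
    malignancy: int = 2,
    mask: np.ndarray | None = None,
    patient_id: str = "P0",
    spacing=(1.0, 1.0, 1.0),
    **biomarkers,
) -> NoduleRecord:
    """Hand-built record with a tiny grid for unit tests."""
    if mask is None:
        mask = np.zeros((6, 6, 4), dtype=bool)
        mask[2:4, 2:4, 1:3] = True
    volume = mask.astype(np.float32) * 2.0
    scores = {name: 3 for name in BIOMARKER_NAMES}
    scores["int_structure"] = 2
    scores.update(biomarkers)
    return NoduleRecord(
        patient_id=patient_id,
        **scores,
        malignancy=malignancy,
        volume=volume,
        mask=mask,
        spacing_mm=spacing,
    )
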