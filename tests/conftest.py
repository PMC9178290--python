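import numpy as np
import pytest

from sensekit.design import LIGAMENTS, ModelBaselines
from sensekit.fe_io import ContactFrame
from sensekit.synth import SyntheticModelConfig


@pytest.fixture
def baselines() -> ModelBaselines:
    return ModelBaselines(
        prestretch={lig: 1.0 for lig in LIGAMENTS},
        youngs_modulus_mpa={lig: 300.0 for lig in LIGAMENTS},
    )


@pytest.fixture
def small_model() -> SyntheticModelConfig:
    return SyntheticModelConfig(model_id="synth01", seed=3)


@pytest.fixture
def tiny_model() -> SyntheticModelConfig:
    """Few faces per patch: fast full-study generation in tests."""
    from sensekit.synth import PatchConfig

    return SyntheticModelConfig(
        model_id="synth01",
        medial_patch=PatchConfig((-22.0, 0.0, 0.0), (12.0, 8.0), 24),
        lateral_patch=PatchConfig((22.0, 0.0, 0.0), (12.0, 8.0), 24),
        seed=3,
    )


def make_frame(pressures, centroids=None, side="medial", time=3.0, face_ids=None):
    """Build a contact frame from a pressure list (test helper)."""
    pressures = np.asarray(pressures, dtype=float)
    n = pressures.size
    if centroids is None:
        centroids = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]).astype(float)
    if face_ids is None:
        face_ids = np.arange(n)
    return ContactFrame(
        time=time, side=side, face_ids=face_ids, centroids=centroids, pressures=pressures
    )
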