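import numpy as np
import pytest

import egohand as eh
from egohand.config import PipelineConfig


@pytest.fixture(scope="session")
def skin_model():
    return eh.default_skin_model()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def verifier(config):
    """Box-verification forest fitted on a small synthetic set."""
    from egohand.pipeline import train_verifier_from_scenes

    return train_verifier_from_scenes(0, config, n_scenes=30)


@pytest.fixture(scope="session")
def one_hand_scene():
    """A short deterministic scene with a left hand holding an object."""
    spec = eh.SceneSpec(seed=42, n_frames=8, coupling="moves_with_hand",
                        entry_side="bottom-left")
    frames, truth = eh.generate_scene(spec)
    return spec, frames, truth


def make_frame(pixels):
    """Wrap a raw uint8 array as a frame at 30 fps."""
    return eh.Frame(pixels=np.asarray(pixels, dtype=np.uint8), index=0,
                    fps=30.0)
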