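import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

from biosense import session_io, synthetic


@pytest.fixture(scope="session")
def example_text() -> str:
    """The bundled nine-image example response file."""
    return session_io.example_response_text()


@pytest.fixture(scope="session")
def small_session() -> synthetic.SessionData:
    """A small simulated session (8 participants, 9 stimuli, 3 classes)."""
    return synthetic.generate_session(
        synthetic.image_scenario(seed=11, n_participants=8)
    )


@pytest.fixture(scope="session")
def pulse_clip():
    """A 30-s noiseless 72-bpm clip on small frames, with its truth."""
    return synthetic.generate_face_video(
        72.0, 30.0, snr_db=np.inf, seed=5, frame_size=(64, 80)
    )
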