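import pytest

import ecgdelin as ed
from ecgdelin.segment import windows_to_arrays

# reduced-scale training recipe shared by the delineation-quality and
# end-to-end screening tests: canonical conv stack, 48 LSTM units per
# direction, 15 epochs of Adam at 2e-3
REDUCED_SCALE = dict(
    conv_filters=(8, 16, 32, 64),
    units_per_direction=48,
    epochs=15,
    learning_rate=2e-3,
    batch_size=32,
    random_state=0,
    validation_fraction=0.0,
)


@pytest.fixture(scope="session")
def trained_estimator():
    """Delineator trained once on 500 seeded synthetic windows."""
    windows = ed.generate_training_windows(500, seed=11)
    X, y = windows_to_arrays(windows)
    return ed.CnnBiLstmDelineator(**REDUCED_SCALE).fit(X, y)


@pytest.fixture(scope="session")
def heldout_windows():
    """100 fresh labeled windows from records the model never saw."""
    return ed.generate_training_windows(100, seed=777)
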