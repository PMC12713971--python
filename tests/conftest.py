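import numpy as np
import pytest

from specscore import (
    EEGRecording,
    StageScript,
    cycle_script,
    design_wavelets,
    generate_night,
)

FS = 500.0


@pytest.fixture(scope="session")
def bank():
    return design_wavelets()


@pytest.fixture(scope="session")
def small_bank():
    """Coarser grid over a narrower range; fast for unit tests."""
    return design_wavelets(0.5, 40.0, 40, 3, 12)


def make_tone(freq, duration=60.0, amplitude=1.0, fs=FS, label="A"):
    t = np.arange(0, duration, 1.0 / fs)
    return EEGRecording(
        (amplitude * np.sin(2 * np.pi * freq * t))[None, :], fs, [label]
    )


@pytest.fixture(scope="session")
def short_night():
    """20-min synthetic night covering all five stages (session-cached)."""
    script = StageScript(
        segments=[
            ("WAKE", 120), ("LIGHT", 240), ("HIDEEP", 240),
            ("LODEEP", 240), ("LIGHT", 120), ("REM", 240),
        ],
        fs=250.0,
        seed=7,
    )
    return generate_night(script)


@pytest.fixture(scope="session")
def full_night():
    """One full 7.5-h cycle-structured night at 500 Hz (session-cached)."""
    return generate_night(cycle_script(seed=11))
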