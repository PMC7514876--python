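import numpy as np
import pytest

from attnalloc import BAS_PROFILE, ValueProfile

#: Printed reference predictions (%) for the four-section monitoring profile.
MATSUI_PERCENT = np.array([4.29, 17.13, 39.97, 38.61])
PROPOSED_PERCENT = np.array([2.35, 10.58, 35.73, 51.34])

#: Published group means (%) of the keypress- and fixation-derived attention
#: vectors from the reference 14-participant experiment (used only as fixed
#: numeric inputs to the statistics layer — they are participant data and
#: cannot be regenerated).
KEYPRESS_MEANS_PERCENT = np.array([6.29, 11.56, 35.34, 46.81])
EYETRACK_MEANS_PERCENT = np.array([5.77, 8.47, 34.78, 50.98])


@pytest.fixture
def bas_profile() -> ValueProfile:
    return BAS_PROFILE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
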