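import numpy as np
import pytest

from timbrekit import audio, descriptors, synth

FS = 44_100


@pytest.fixture(scope="session")
def filterbank():
    return audio.design_filterbank()


@pytest.fixture(scope="session")
def stimulus_bank():
    """Fourteen synthetic recordings plus their category table (seed 7)."""
    return synth.make_stimulus_bank(seed=7)


@pytest.fixture(scope="session")
def recording_table(stimulus_bank):
    bank, _ = stimulus_bank
    return descriptors.descriptor_table(bank)


@pytest.fixture(scope="session")
def mixed_set(stimulus_bank):
    """Seven recordings + seven transformations with class labels."""
    bank, cats = stimulus_bank
    trans = synth.make_transformation_bank(bank, 7, seed=7)
    rec = bank[:7]
    classes = {s.label: "recording" for s in rec}
    classes.update({s.label: "transformation" for s in trans})
    table = descriptors.descriptor_table(rec + trans)
    return table, classes, cats


def tone(freq: float, n: int = 22050, amp: float = 1.0,
         fs: int = FS, label: str = "tone") -> audio.Signal:
    t = np.arange(n) / fs
    return audio.Signal(amp * np.sin(2 * np.pi * freq * t), fs, label)
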