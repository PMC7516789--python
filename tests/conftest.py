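import numpy as np
import pytest

import vowelbayes as vb

TRUE_B = (54.0, 22.0, 19.0)
TRUE_F = (430.0, 1088.0, 2142.0)


def male_vowel_spec(f0_hz: float = 120.0, seed: int = 1, **kw) -> vb.VowelSynthesisSpec:
    """The standard synthetic test vowel: three formants, modest jitter/shimmer."""
    return vb.VowelSynthesisSpec(
        f0_hz=f0_hz,
        formants=tuple(zip(TRUE_B, TRUE_F)),
        seed=seed,
        **kw,
    )


def periods_from_vowel(vow: vb.SyntheticVowel) -> vb.PitchPeriodSet:
    seg = vb.SpeechSegment(samples=vow.waveform, fs=vow.spec.fs_out)
    return vb.segment_periods(seg, vb.GCISequence(times=vow.gci_times))


@pytest.fixture(scope="session")
def male_vowel() -> vb.SyntheticVowel:
    return vb.synthesize_vowel(male_vowel_spec())


@pytest.fixture(scope="session")
def male_periods(male_vowel) -> vb.PitchPeriodSet:
    return periods_from_vowel(male_vowel)


@pytest.fixture(scope="session")
def gamma_prior() -> vb.PriorConfig:
    return vb.PriorConfig.preset("gamma")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
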