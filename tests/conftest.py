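import numpy as np
import pytest

from leadtime import decode, spectral, synth


@pytest.fixture(scope="session")
def effect_epochs():
    """Two-lead recording: one planted-effect lead (L000), one null lead (L001)."""
    cfg = synth.SynthConfig(
        n_trials=70,
        n_leads=2,
        area_assignment=("EFF", "NULL"),
        effects={"EFF": synth.AreaEffect(onset=-0.2, band=(25, 45), amplitude=0.85)},
        noise=synth.NoiseSpec(white_amplitude=0.05),
        seed=11,
    )
    trials = synth.generate_task_sequence(cfg)
    epochs, truth = synth.generate_recording(trials, cfg)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def effect_power(effect_epochs):
    _, epochs, _ = effect_epochs
    return spectral.wavelet_power(epochs, spectral.SpectralConfig(f_min=15, f_max=60, n_scales=8))


@pytest.fixture(scope="session")
def quick_decode_config():
    return decode.DecodeConfig(n_repeats=2, n_permutations=0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
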