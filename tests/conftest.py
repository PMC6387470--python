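import numpy as np
import pytest

from albuminbind import SynthConfig, gen_band_spectra


@pytest.fixture
def noise_free():
    return SynthConfig(seed=0, noise_model="none", noise_level=0.0)


@pytest.fixture
def band_spectra():
    """Noise-free donor emission / acceptor extinction Gaussian bands."""
    return gen_band_spectra(cfg=SynthConfig(seed=0))


@pytest.fixture
def gaussian_spectrum_factory():
    def make(center=340.0, sd=15.0, amplitude=1.0, grid=None, kind="fluorescence_au"):
        from albuminbind import Spectrum

        if grid is None:
            grid = np.arange(250.0, 451.0, 1.0)
        grid = np.asarray(grid, dtype=float)
        sig = amplitude * np.exp(-0.5 * ((grid - center) / sd) ** 2)
        return Spectrum(grid, sig, signal_kind=kind, label=f"gauss{center}")

    return make
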