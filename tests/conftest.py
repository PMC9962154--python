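import numpy as np
import pytest

import veinscan as vs


@pytest.fixture(scope="session")
def phantom():
    """Default-geometry phantom, seed 1."""
    return vs.generate_phantom(1)


@pytest.fixture(scope="session")
def bank(phantom):
    return vs.default_diode_bank(phantom.shape)


@pytest.fixture(scope="session")
def default_sim():
    """2 s of default-geometry noise-free acquisition (66 complete cycles)."""
    cfg = vs.RunConfig(frames=260)
    return vs.simulate(cfg)


@pytest.fixture(scope="session")
def small_run_config():
    """Reduced-geometry configuration for fast end-to-end runs; identical
    timing and optical model, proportionally smaller frames."""
    geo = vs.Geometry(rows=130, cols=240, finger_col_stop=192)
    return vs.RunConfig(
        frames=260,
        geometry=geo,
        timing=vs.TimingConfig(rows=130),
    )


def single_pixel_phantom(mu_tissue=0.5, mu_blood=0.0, tissue=1.0, vein=0.0,
                         amplitude=0.0, rate_bpm=90.0, shape=(1, 1)):
    """Tiny hand-built phantom for closed-form render checks."""
    mask = np.ones(shape, dtype=bool)
    return vs.FingerPhantom(
        finger_mask=mask,
        vein_depth_map=np.full(shape, vein, dtype=float),
        tissue_depth_map=np.full(shape, tissue, dtype=float),
        texture_map=np.ones(shape, dtype=float),
        nail_mask=np.zeros(shape, dtype=bool),
        absorption={940.0: (mu_tissue, mu_blood),
                    875.0: (mu_tissue, mu_blood),
                    730.0: (mu_tissue, mu_blood),
                    830.0: (mu_tissue, mu_blood)},
        pulse=vs.PulseParams(rate_bpm=rate_bpm, amplitude=amplitude),
    )


def uniform_bank(position=(0.0, 0.0), sigma=1e9, power=1.0,
                 wavelengths=(940.0, 875.0, 730.0)):
    """Bank with all 12 sources co-located, unit falloff, equal powers."""
    return vs.DiodeBank(
        positions=tuple(position for _ in range(12)),
        wavelengths_by_row={0: wavelengths[0], 1: wavelengths[1], 2: wavelengths[2]},
        powers_by_row={0: 1.0, 1: 1.0, 2: 1.0},
        falloff_sigma=sigma,
        source_scale=power,
    )
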