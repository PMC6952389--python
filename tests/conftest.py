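import numpy as np
import pytest

from adhescan.synthetic import PopulationConfig, generate_ws_stack
from adhescan.thresholds import SaturationThresholdModel


@pytest.fixture(scope="session")
def reference_at_model() -> SaturationThresholdModel:
    """Saturation-threshold law at the reference parameters a=3128, b=2935 pm."""
    return SaturationThresholdModel(3128.0, 2935.0)


@pytest.fixture(scope="session")
def single_cell_run():
    """A noiseless, well-sampled single cell plus its ground truth.

    The footprint is large relative to the 25 µm pitch (σ/pitch ≈ 3.6) so
    the bilinear reconstruction of the bump is accurate and the pipeline
    can be compared quantitatively against the closed-form truth.
    """
    cfg = PopulationConfig(
        n_cells=1,
        noise_sd=0.0,
        amplitude_sigma_log=0.0,
        amplitude_mu_log=np.log(2600.0),
        footprint_mean_um=225.0,
        footprint_sd_um=0.0,
        footprint_range_um=(225.0, 225.0),
        duration=3600.0,
        frame_interval=120.0,
        seed=11,
    )
    stack, truth, masks = generate_ws_stack(cfg)
    return cfg, stack, truth, masks


@pytest.fixture(scope="session")
def small_population_run():
    """A 40-cell noisy population on the default sensor geometry."""
    cfg = PopulationConfig(n_cells=40, duration=1800.0, frame_interval=60.0, seed=23)
    stack, truth, masks = generate_ws_stack(cfg)
    return cfg, stack, truth, masks
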