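"""Shared fixtures: simulated bases, masks and (session-scoped) trained
desk models reused across the unit and acceptance tests."""

import numpy as np
import pytest

from lcosyforge.dunet_models import (ModelConfig, TrainConfig, build_dunet,
                                     train_model)
from lcosyforge.nus import reference_mask
from lcosyforge.spin_simulator import (SequenceParams, SpinSystem,
                                       build_basis_set, load_spin_system,
                                       simulate_lcosy_fid)
from lcosyforge.synthesizer import generate_dataset

#: Test-suite training scales: the reconstruction checks pass at a reduced
#: smoke scale; the quantitation fixture trains near the desk scale because
#: the attribution behavior only emerges with enough updates.
SMOKE_N_TRAIN = 320
SMOKE_EPOCHS = 8
QUANT_N_TRAIN = 500
QUANT_EPOCHS = 14


@pytest.fixture(scope="session")
def params():
    return SequenceParams()


@pytest.fixture(scope="session")
def small_params():
    """Reduced direct-dimension grid for fast simulator-level tests."""
    return SequenceParams(n_t2=256, n_t1=32)


@pytest.fixture(scope="session")
def basis(params):
    return build_basis_set(params=params)


@pytest.fixture(scope="session")
def water_fid(params):
    return simulate_lcosy_fid(load_spin_system("Water"), params)


@pytest.fixture(scope="session")
def mask4():
    return reference_mask(25)


@pytest.fixture(scope="session")
def single_spin_system():
    return SpinSystem("one", (3.0,), np.zeros((1, 1)))


@pytest.fixture(scope="session")
def ax_system():
    j = np.array([[0.0, 7.0], [7.0, 0.0]])
    return SpinSystem("AX", (3.0, 2.0), j)


@pytest.fixture(scope="session")
def recon_model(basis, mask4):
    """Desk-architecture reconstruction model trained at smoke scale."""
    ds = generate_dataset(SMOKE_N_TRAIN, "recon", basis, mask=mask4, seed=301)
    cfg = ModelConfig(out_channels=3, depth=5, base_filters=4, growth=4)
    model = build_dunet(cfg, seed=0)
    trained = train_model(model, ds,
                          TrainConfig(epochs=SMOKE_EPOCHS, seed=0))
    trained.task = "recon"
    return trained


@pytest.fixture(scope="session")
def quant_model(basis):
    """Desk-architecture quantitation model trained at smoke scale."""
    ds = generate_dataset(QUANT_N_TRAIN, "quant", basis, seed=302)
    cfg = ModelConfig(out_channels=17, depth=5, base_filters=4, growth=4,
                      io_gain=100.0, nonneg_channels=tuple(range(17)))
    model = build_dunet(cfg, seed=0)
    trained = train_model(model, ds,
                          TrainConfig(epochs=QUANT_EPOCHS, seed=0))
    trained.task = "quant"
    return trained
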