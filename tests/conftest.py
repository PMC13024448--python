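"""Shared fixtures: small phantoms and the smoke-scale trained pipelines."""

import numpy as np
import pytest

from myostrain import (NetworkConfig, PhantomSpec, TrainConfig, make_phantom,
                      smoke_spec)
from myostrain.cli import run_pipeline

SMOKE_SEED = 0


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Full-scale (128x128, 20-frame) phantom with analytic ground truth."""
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom for fast unit tests."""
    spec = smoke_spec()
    return spec, make_phantom(spec)


def _run_smoke(variant: str):
    base = smoke_spec()
    net = NetworkConfig(variant=variant, base_channels=8)
    cfg = TrainConfig(epochs=30, seed=SMOKE_SEED)
    return run_pipeline(8, base, net, cfg, seed=SMOKE_SEED)


@pytest.fixture(scope="session")
def smoke_myonet():
    """MyoNet trained 30 epochs on the 8-scan 32x32 smoke cohort."""
    return _run_smoke("myonet")


@pytest.fixture(scope="session")
def smoke_resmyonet():
    """ResMyoNet trained on the identical smoke fixture."""
    return _run_smoke("resmyonet")


def pooled_strain_vs_analytic(result):
    """Pool predicted vs analytic segment strains over test slices and frames."""
    pred, analytic = [], []
    for r in result["test_results"]:
        pt = r["pred_tables"]
        tr = r["truth"].segment_table_percent()
        m = pt[pt.segment > 0].merge(tr, on=["frame", "segment"])
        pred += list(m["Ecc_percent_x"]) + list(m["Err_percent_x"])
        analytic += list(m["Ecc_percent_y"]) + list(m["Err_percent_y"])
    return np.asarray(pred), np.asarray(analytic)
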