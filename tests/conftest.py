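import numpy as np
import pytest

from pathscore.sta_engine import (
    PathwayModel,
    ProbesetEmission,
    ScoreNormalization,
    TargetGene,
    build_model,
    calibrate,
)
from pathscore.synthetic_data import simulate_calibration_set, simulation_panel


@pytest.fixture(scope="session")
def two_gene_model():
    """Tiny hand-parameterised model: 2 up-responsive genes × 1 probeset."""
    return PathwayModel(
        pathway_name="toy",
        prior_active=0.4,
        genes=(
            TargetGene(
                symbol="A",
                direction="up",
                p_tx_given_active=0.85,
                p_tx_given_inactive=0.15,
                probesets=(ProbesetEmission("A_ps1", 5.0, 8.0, 0.7),),
            ),
            TargetGene(
                symbol="B",
                direction="up",
                p_tx_given_active=0.9,
                p_tx_given_inactive=0.2,
                probesets=(ProbesetEmission("B_ps1", 4.0, 6.5, 1.1),),
            ),
        ),
        normalization=ScoreNormalization(-6.0, 6.0),
    )


@pytest.fixture(scope="session")
def calibrated_model():
    """Model calibrated on a noisy synthetic calibration set (25+25)."""
    panel = simulation_panel()
    reference = build_model(panel)
    training = simulate_calibration_set(reference, 25, 25, noise_sd=0.5, seed=11)
    return calibrate(panel, training)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
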