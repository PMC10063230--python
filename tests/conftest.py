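import numpy as np
import pytest

from perturbscape.fc import compute_fc
from perturbscape.priors import build_membership_prior
from perturbscape.synthetic import (
    SyntheticSpec,
    generate_connectome,
    generate_region_metadata,
)
from perturbscape.vae import VAEConfig, train_vae


@pytest.fixture(scope="session")
def world20():
    """Desk-scale synthetic study: 20-region connectome, metadata, prior, omega."""
    spec = SyntheticSpec(seed=0)
    conn = generate_connectome(spec)
    meta = generate_region_metadata(spec)
    M = build_membership_prior(meta.labels)
    omega = 2.0 * np.pi * meta.natural_frequencies
    return {"spec": spec, "conn": conn, "meta": meta, "M": M, "omega": omega}


@pytest.fixture(scope="session")
def random_fc_dataset():
    """Cheap valid FC matrices (correlations of random series), 12 regions."""
    rng = np.random.default_rng(3)
    return [compute_fc(rng.standard_normal((12, 120))) for _ in range(160)]


@pytest.fixture(scope="session")
def tiny_vae(random_fc_dataset):
    """A small trained model for encode/decode plumbing tests."""
    cfg = VAEConfig(input_dim=66, encoder_widths=(64, 16), batch_size=32, epochs=8, seed=4)
    return train_vae(random_fc_dataset, cfg)
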