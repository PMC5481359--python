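import numpy as np
import pytest

from zsdecode import SyntheticConfig, TrialTable, generate_dataset


@pytest.fixture(scope="session")
def small_data():
    """Modest 12-class / 3-block dataset with planted signal (snr 3)."""
    cfg = SyntheticConfig(n_classes=12, n_blocks=3, p_attributes=20, m_total=80,
                          n_informative=15, snr=3.0, block_drift_sd=0.2, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_data():
    """Perfectly separable construction: every feature informative, no noise."""
    cfg = SyntheticConfig(n_classes=15, n_blocks=3, p_attributes=10, m_total=100,
                          n_informative=100, snr=np.inf, block_drift_sd=0.0, seed=3)
    return generate_dataset(cfg)


def permute_labels_within_blocks(table: TrialTable, rng) -> TrialTable:
    """Shuffle class labels within each block, preserving the balanced design
    but destroying any attribute-feature association."""
    cls = table.class_ids.copy()
    for b in np.unique(table.block_ids):
        idx = np.flatnonzero(table.block_ids == b)
        cls[idx] = cls[idx[rng.permutation(len(idx))]]
    return TrialTable(table.features, cls, table.block_ids, table.feature_meta)
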