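import numpy as np
import pandas as pd
import pytest

from scm6a.config import QuantConfig, SimConfig


@pytest.fixture
def small_sim_cfg():
    return SimConfig(n_cells=100, n_regulators=20, n_sites=10,
                     regulators_per_site=2, n_transcripts=10, seed=42)


@pytest.fixture
def quant_cfg():
    return QuantConfig()


@pytest.fixture
def annotation():
    """Three transcripts with round region lengths."""
    return pd.DataFrame({
        "transcript_id": ["tx_a", "tx_b", "tx_c"],
        "gene_id": ["GA", "GB", "GC"],
        "utr5_len": [100, 200, 100],
        "cds_len": [600, 1000, 400],
        "utr3_len": [300, 400, 200],
        "strand": ["+", "-", "+"],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(0)
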