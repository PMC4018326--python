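import pandas as pd
import pytest

from matriquant.simulate import SimulationConfig, simulate_dataset


def make_panel(rows):
    """Panel frame from (accession, length, conc_acl, conc_pt, fc_acl, fc_pt, std)."""
    frame = pd.DataFrame(rows, columns=["accession", "length", "conc_acl",
                                        "conc_pt", "sex_fc_acl", "sex_fc_pt",
                                        "is_standard"])
    return frame.set_index("accession")


SMALL_PANEL = make_panel([
    ("ADH1_YEAST", 300, 25, 25, 1.0, 1.0, True),
    ("CO1A1_HUMAN", 400, 200, 400, 1.0, 1.0, False),
    ("CO1A2_HUMAN", 400, 100, 200, 1.0, 1.0, False),
    ("CO3A1_HUMAN", 400, 150, 50, 1.0, 1.0, False),
    ("ALBU_HUMAN", 300, 10, 6, 2.0, 2.0, False),
    ("LUM_HUMAN", 300, 10, 5, 1.0, 1.0, False),
])


def clean_config(panel=None, **overrides):
    """Noise-free generator settings: every estimator should be exact."""
    defaults = dict(panel=SMALL_PANEL.copy() if panel is None else panel,
                    sigma=0.0, bio_sigma=0.0, run_scale_sigma=0.0,
                    dropout=0.0, decoy_rate=0.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_panel():
    return SMALL_PANEL.copy()


@pytest.fixture
def clean_dataset():
    """Small noise-free dataset: 6 proteins, 14 runs, no decoys/dropout."""
    return simulate_dataset(clean_config(), seed=11)


@pytest.fixture
def noisy_dataset():
    """Small dataset with all noise sources and decoys on."""
    cfg = SimulationConfig(panel=SMALL_PANEL.copy(), sigma=0.15, bio_sigma=0.2,
                           run_scale_sigma=0.1, dropout=0.05, decoy_rate=0.05)
    return simulate_dataset(cfg, seed=7)
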