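import warnings

import pytest

from ambignorm import nlm_metrics as nm
from ambignorm import synthetic_data as syn


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # boundary (zero) random-intercept variance is expected for toy data
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*singular fit.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def zeugma_items():
    """40 zeugma items (10 per condition), single-word anaphors."""
    return syn.generate_zeugma_items(10, seed=3)


@pytest.fixture(scope="session")
def toy_encoder(zeugma_items):
    cfg = syn.ToyEncoderConfig(n_layers=3, dim=24, seed=5)
    return syn.make_toy_encoder(cfg, zeugma_items)


@pytest.fixture(scope="session")
def toy_metrics(zeugma_items, toy_encoder):
    return nm.compute_item_metrics(toy_encoder, zeugma_items)


@pytest.fixture(scope="session")
def rating_study():
    """Default-condition rating study with 3 planted flat raters, seed 7."""
    cfg = syn.RatingStudyConfig(seed=7, n_flat_raters=3)
    return syn.simulate_rating_study(cfg)
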