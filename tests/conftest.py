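import pytest

from sycodiv.data_model import Marker
from sycodiv.synthetic_data import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def study_system():
    """One study-structured synthetic community (no missing markers)."""
    cfg = CommunityConfig.study_system(seed=3, missing_fraction=0.0)
    dataset, truth = simulate_community(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tight_community():
    """Community generated under a wide intra/inter distance separation.

    theta = 0.002 keeps the intraspecific tail far below the 3% cutoff while
    sister pairs sit near 10%: realized separation is several-fold.
    """
    cfg = CommunityConfig.study_system(seed=7, missing_fraction=0.0, theta=0.002)
    dataset, truth = simulate_community(cfg)
    return cfg, dataset, truth


@pytest.fixture()
def coi_alignment(study_system):
    return study_system[1].alignments[Marker.COI]
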