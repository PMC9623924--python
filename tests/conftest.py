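import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctds import simulate_proteome

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def random_proteins():
    """A small reproducible random proteome for decoy/digest properties."""
    return simulate_proteome(60, 200, seed=42)


def make_psms(
    n_targets,
    n_decoys,
    target_counts=(1, 1),
    decoy_counts=(1, 1),
    target_scores=None,
    decoy_scores=None,
):
    """Build a rank-1 PSM frame with uniform candidate counts per label."""
    rows = []
    for i in range(n_targets):
        rows.append(
            dict(
                spectrum_id=f"T{i:04d}",
                rank=1,
                peptide="PEPTIDE",
                score=target_scores[i] if target_scores is not None else 100.0 - i,
                label="target",
                target_count=target_counts[0],
                decoy_count=target_counts[1],
            )
        )
    for i in range(n_decoys):
        rows.append(
            dict(
                spectrum_id=f"D{i:04d}",
                rank=1,
                peptide="PEPTIDE",
                score=decoy_scores[i] if decoy_scores is not None else 50.0 - i,
                label="decoy",
                target_count=decoy_counts[0],
                decoy_count=decoy_counts[1],
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture
def psm_builder():
    return make_psms


@pytest.fixture
def rng():
    return np.random.default_rng(7)
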