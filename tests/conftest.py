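import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phosphodelta.io import PhosphopeptideMeasurement, ProteinSequenceRecord

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_measurement(
    sequence="AKSPTLR",
    method="TiSH",
    hl_ratio=0.5,
    sites=((3, "S"),),
    probs=None,
    protein="P00001",
    q_value=0.005,
):
    """Convenience builder for a valid measurement."""
    positions = [p for p, _ in sites]
    residues = [r for _, r in sites]
    return PhosphopeptideMeasurement(
        sequence=sequence,
        method=method,
        hl_ratio=hl_ratio,
        site_positions=positions,
        site_residues=residues,
        localization_probs=list(probs) if probs else [0.99] * len(sites),
        protein_acc=protein,
        q_value=q_value,
    )


@pytest.fixture
def tiny_proteome():
    return {
        "P00001": ProteinSequenceRecord("P00001", "AKSPTLRMMGGSDDE"),
        "P00002": ProteinSequenceRecord("P00002", "MSTYKEDEAKSPTLRWWW"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
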