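import numpy as np
import pytest

from fluorosim import (
    ErrorParams,
    Peptide,
    ProteinRecord,
    generate_synthetic_proteome,
    human_like_composition,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_peptides():
    """The Fig-5-style toy world: peptides X and Y as whole Cys-anchored
    proteins, plus the error-demo peptide GKEGK sequenced freely."""
    return {
        "X": Peptide("GKEGC", "PX", anchor_index=5),
        "Y": Peptide("GKGKEC", "PY", anchor_index=6),
        "swap_demo": Peptide("GKEGK", "PD", anchor_index=None),
        "fig1": Peptide("WKKAY", "PF", anchor_index=None),
    }


@pytest.fixture
def toy_proteome():
    return [ProteinRecord("PX", "GKEGC"), ProteinRecord("PY", "GKGKEC")]


@pytest.fixture(scope="session")
def small_proteome():
    """50 human-like synthetic proteins for integration-style tests."""
    return generate_synthetic_proteome(
        50, composition=human_like_composition(), seed=42
    )
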