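import numpy as np
import pytest

from bindspec import (
    QuenchingGroundTruth,
    canonical_cd_basis,
    simulate_quenching_titration,
)


@pytest.fixture(scope="session")
def basis():
    return canonical_cd_basis()


@pytest.fixture
def noiseless_series():
    """Factory for noiseless emission titrations with known (Kb, n)."""

    def make(kb=5200.0, n=1.0, temperature=298.0, **kwargs):
        truth = QuenchingGroundTruth(
            kb_per_T={temperature: kb}, n=n, noise_sd=0.0, **kwargs
        )
        return simulate_quenching_titration(truth, temperature)

    return make


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A complete noiseless synthetic study bundle (written once per session)."""
    from bindspec.bundle import write_fixture_bundle

    directory = tmp_path_factory.mktemp("bundle")
    config_path = write_fixture_bundle(directory, seed=7)
    return directory, config_path


@pytest.fixture
def straight_line_spectrum():
    from bindspec import Spectrum

    axis = np.arange(300.0, 501.0, 10.0)
    return Spectrum(axis, 2.0 * axis - 100.0, "emission")
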