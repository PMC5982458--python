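import numpy as np
import pandas as pd
import pytest

import feedscreen as fs


@pytest.fixture(scope="session")
def config():
    return fs.ProtocolConfig()


@pytest.fixture(scope="session")
def normalizer(config):
    return fs.ProfileNormalizer(config)


@pytest.fixture(scope="session")
def reference_vectors(config, normalizer):
    """Normalized simulated commercial-filament stand-ins (fixed seed)."""
    panel = fs.make_reference_library(config, seed=3)
    return [normalizer.transform_one(p) for p in panel.profiles]


@pytest.fixture(scope="session")
def reference_library(reference_vectors):
    return fs.build_reference_library(reference_vectors)


@pytest.fixture
def write_csv(tmp_path):
    """Write rows of (distance, force, phase) to a canonical profile CSV."""

    def _write(rows, name="specimen__rep1.csv"):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=["distance_mm", "force_N", "phase"])
        df.to_csv(path, index=False)
        return path

    return _write


def make_profile(distances, forces, phases, filament_id="x", replicate=1):
    """Build a FlexibilityProfile directly from arrays."""
    samples = pd.DataFrame(
        {
            "distance_mm": np.asarray(distances, float),
            "force_N": np.asarray(forces, float),
            "phase": list(phases),
        }
    )
    return fs.FlexibilityProfile(
        filament_id=filament_id, replicate=replicate, samples=samples
    )
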