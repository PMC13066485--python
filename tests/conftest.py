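import numpy as np
import pytest

from assaydiff.io_model import Dataset, PairedSample, Sex
from assaydiff.synthetic import SyntheticConfig, generate


def make_dataset(rows, provenance="test"):
    """rows: iterable of (age, sex, clia, lcms)."""
    samples = tuple(
        PairedSample(
            sample_id=f"T{i:04d}",
            age=float(age),
            sex=sex if isinstance(sex, Sex) else Sex(sex),
            clia=float(clia),
            lcms=float(lcms),
        )
        for i, (age, sex, clia, lcms) in enumerate(rows)
    )
    return Dataset(samples=samples, provenance=provenance)


@pytest.fixture(scope="session")
def study_cohort():
    """A mid-sized synthetic cohort under the study's default conditions."""
    return generate(SyntheticConfig(n=200, seed=42))


@pytest.fixture(scope="session")
def blob_fixture():
    """30 points in 2-D from three well-separated blobs (10 each)."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [6.0, 0.5], [3.0, 7.0]])
    X = np.vstack([c + rng.normal(0, 0.5, size=(10, 2)) for c in centers])
    return X
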