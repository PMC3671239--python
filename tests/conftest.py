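import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phavip as p

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def write_fasta_text(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def random_records():
    """Factory for n valid random protein records."""

    def _make(n, seed=0, min_len=5, max_len=40, prefix="r"):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            seq = "".join(rng.choice(list(p.STANDARD_AA), size=length))
            records.append(p.ProteinRecord(id=f"{prefix}{i}", sequence=seq))
        return records

    return _make


@pytest.fixture
def labelled_matrix():
    """Factory for a small labelled FeatureMatrix of raw numeric features."""

    def _make(values, labels, names=None):
        values = np.asarray(values, dtype=float)
        if names is None:
            names = p.CANONICAL_FEATURE_NAMES[: values.shape[1]]
        return p.FeatureMatrix(
            values=values,
            ids=tuple(f"s{i}" for i in range(values.shape[0])),
            feature_names=tuple(names),
            labels=np.asarray(labels, dtype=int),
        )

    return _make


@pytest.fixture
def separable_dataset():
    """A small synthetic dataset with a strong compositional class signal."""
    config = p.GeneratorConfig(
        n_pos=20, n_neg=20, length_range=(40, 80), effect_size=0.35, seed=7
    )
    return p.sample_dataset(config)
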