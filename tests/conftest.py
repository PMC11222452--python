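import numpy as np
import pytest

import plastidkit as pk


@pytest.fixture(scope="session")
def markers_dataset():
    """Clean 12-species single-accession dataset with one planted 5x gene."""
    return pk.simulate_dataset(pk.default_params("markers", seed=101))


@pytest.fixture(scope="session")
def paperlike_dataset():
    """Nine-species / 18-accession dataset with indels and IR contractions."""
    return pk.simulate_dataset(pk.default_params("paperlike", seed=7))


def random_alignment(rng, n_rows=5, n_cols=400, gap_frac=0.05,
                     n_frac=0.02, diversity=0.1):
    """Random gapped alignment around a common ancestor sequence."""
    base = rng.integers(0, 4, size=n_cols)
    rows = {}
    for i in range(n_rows):
        seq = base.copy()
        mut = rng.random(n_cols) < diversity
        seq[mut] = rng.integers(0, 4, size=int(mut.sum()))
        chars = np.array(list("ACGT"))[seq].astype(object)
        chars[rng.random(n_cols) < gap_frac] = "-"
        chars[rng.random(n_cols) < n_frac] = "N"
        rows[f"t{i}"] = "".join(chars)
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
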