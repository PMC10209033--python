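import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aspmine.dataset import ProteinDataset, ProteinRecord
from aspmine.synthetic import PlantedMotif, generate_dataset, small_profile

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(rows):
    """rows: iterable of (id, sequence, category, label)."""
    return ProteinDataset(ProteinRecord(*r) for r in rows)


def random_dataset(rng, n_proteins=20, length_range=(10, 30), n_categories=3,
                   alphabet="ACDEFGHIKL"):
    """Unstructured random dataset for oracle-equivalence tests."""
    rows = []
    letters = np.array(list(alphabet))
    for i in range(n_proteins):
        length = int(rng.integers(*length_range))
        seq = "".join(rng.choice(letters, size=length))
        cat = f"cat{int(rng.integers(n_categories))}"
        label = 1 if rng.random() < 0.5 else -1
        rows.append((f"p{i}", seq, cat, label))
    # ensure both classes are present
    if all(r[3] == 1 for r in rows):
        rows[0] = (rows[0][0], rows[0][1], rows[0][2], -1)
    if all(r[3] == -1 for r in rows):
        rows[0] = (rows[0][0], rows[0][1], rows[0][2], 1)
    return make_dataset(rows)


@pytest.fixture
def tiny_dataset():
    return make_dataset([
        ("a1", "MKRREL", "wheat", 1),
        ("a2", "KRRE", "wheat", -1),
        ("a3", "PSQQW", "apple", 1),
    ])


@pytest.fixture
def planted_fixture():
    """Small category profile with one strong allergen-only motif shared
    across paired and positive-only categories."""
    config = small_profile(seed=11, motifs=(PlantedMotif("WQHKW", 0.9, 0.0),))
    return generate_dataset(config)
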