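import numpy as np
import pytest

from tadip import AlignmentTable, HitRecord


def make_table(hits, lengths=None):
    """Build an AlignmentTable from (read, genome, M, L) tuples."""
    return AlignmentTable.from_records(
        HitRecord(r, g, "", m, l) for r, g, m, l in hits
    )


def random_instance(rng, n=6, k=2, L=20):
    """Small random dense-ish instance for oracle checks."""
    records = []
    for j in range(n):
        cands = rng.choice(k, size=rng.integers(1, k + 1), replace=False)
        for i in cands:
            m = int(rng.integers(int(0.6 * L), L + 1))
            records.append(HitRecord(f"r{j}", f"g{i}", "", m, L))
    return AlignmentTable.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_genome_table():
    return make_table(
        [
            ("r1", "gA", 9, 10),
            ("r1", "gB", 8, 10),
            ("r2", "gA", 10, 10),
        ]
    )
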