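import numpy as np
import pytest

from diplohmm.matrix import GAP, AlignmentMatrix


def make_matrix(rows, site_alleles=None, weight=30.0, positions=None):
    """Build a small matrix from strings like ["GGT", "-GT"].

    '-' is a gap; every other character must appear in the column's allele
    set.  Default allele sets are derived from the observed characters
    (padded with an alternative to stay at least bi-allelic).
    """
    m, n = len(rows), len(rows[0])
    if site_alleles is None:
        site_alleles = []
        for j in range(n):
            seen = sorted({r[j] for r in rows} - {"-"})
            if len(seen) < 2:
                extra = "T" if seen and seen[0] != "T" else "G"
                seen = seen + [extra]
            site_alleles.append(tuple(seen))
    entries = np.full((m, n), GAP, dtype=np.int16)
    weights = np.zeros((m, n))
    for i, r in enumerate(rows):
        for j, ch in enumerate(r):
            if ch == "-":
                continue
            entries[i, j] = site_alleles[j].index(ch)
            weights[i, j] = weight
    if positions is None:
        positions = np.arange(n) * 100
    return AlignmentMatrix(
        entries, weights, positions, site_alleles, [f"r{i}" for i in range(m)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
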