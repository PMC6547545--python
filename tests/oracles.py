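"""Independent brute-force oracles used to validate the dynamic programs.

Everything here enumerates explicitly: bipartitions of all reads via the
powerset, allele assignments per column by direct summation.  No code from
the HMM or graph machinery is reused beyond the shared model primitives
(pair transition table and scalar emission probabilities), which are
themselves unit-tested against closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np

from diplohmm.matrix import GAP, AlignmentMatrix
from diplohmm.substitution import SubstitutionModel


def _column_factor(
    matrix: AlignmentMatrix,
    model: SubstitutionModel,
    part2: set[int],
    j: int,
) -> dict[tuple[int, int], float]:
    """For one global bipartition: per (a1, a2), transition x emission at j."""
    sigma = matrix.site_alleles[j]
    table = model.pair_table(sigma)
    out = {}
    for a1, a2 in itertools.product(range(len(sigma)), repeat=2):
        p = table[a1, a2]
        for i in range(matrix.m):
            if matrix.entries[i, j] == GAP:
                continue
            if not matrix.first_nongap(i) <= j <= matrix.last_nongap(i):
                continue
            hap = a2 if i in part2 else a1
            p *= model.emission_probability(
                sigma[matrix.entries[i, j]],
                sigma[hap],
                matrix.weights[i, j],
                sigma,
            )
        out[(a1, a2)] = p
    return out


def brute_force_inference(matrix: AlignmentMatrix, model: SubstitutionModel):
    """Total likelihood and per-column genotype posteriors by enumeration
    over all 2^m read bipartitions and all allele assignments."""
    m, n = matrix.m, matrix.n
    total = 0.0
    # genotype_mass[j][genotype] accumulates sum over bipartitions
    genotype_mass = [dict() for _ in range(n)]
    for bits in range(1 << m):
        part2 = {i for i in range(m) if (bits >> i) & 1}
        factors = [_column_factor(matrix, model, part2, j) for j in range(n)]
        col_sums = [sum(f.values()) for f in factors]
        like = float(np.prod(col_sums))
        total += like
        for j in range(n):
            rest = like / col_sums[j] if col_sums[j] > 0 else 0.0
            for (a1, a2), p in factors[j].items():
                g = tuple(sorted((a1, a2)))
                genotype_mass[j][g] = genotype_mass[j].get(g, 0.0) + rest * p
    posteriors = [
        {g: v / total for g, v in genotype_mass[j].items()} for j in range(n)
    ]
    return total, posteriors


def random_matrix(
    rng: np.random.Generator,
    m: int,
    n: int,
    alphabet=("A", "C", "G", "T"),
    n_alleles: int = 2,
    max_weight: float = 40.0,
) -> AlignmentMatrix:
    """Random well-formed matrix: contiguous read intervals (with occasional
    internal gaps), random alleles and weights, every row/column covered."""
    while True:
        entries = np.full((m, n), GAP, dtype=np.int16)
        weights = np.zeros((m, n))
        for i in range(m):
            lo = int(rng.integers(0, n))
            hi = int(rng.integers(lo, n))
            for j in range(lo, hi + 1):
                if hi > lo and rng.random() < 0.15 and lo < j < hi:
                    continue  # internal gap
                entries[i, j] = rng.integers(0, n_alleles)
                weights[i, j] = rng.uniform(1.0, max_weight)
        if ((entries == GAP).all(axis=0)).any():
            continue
        base = rng.choice(len(alphabet), size=(n, n_alleles))
        alleles = []
        for j in range(n):
            picks = list(rng.choice(alphabet, size=n_alleles, replace=False))
            alleles.append(tuple(picks))
        return AlignmentMatrix(
            entries,
            weights,
            np.arange(n) * 10,
            alleles,
            [f"r{i}" for i in range(m)],
        )
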