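"""Greedy phase-informative read selection.

Bounds the per-column coverage before HMM construction.  Reads are scored
by the number of candidate heterozygous sites they cover and by their mean
entry weight, then admitted greedily (highest score first) subject to a
per-column capacity cap.  Ties break on read id for determinism.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .matrix import GAP, AlignmentMatrix


def candidate_het_columns(
    matrix: AlignmentMatrix, min_minor_fraction: float = 0.25, min_minor_count: int = 2
) -> list[int]:
    """Columns whose pileup suggests heterozygosity (minor allele well
    supported); used to score phase informativeness when no candidate list
    is supplied."""
    out = []
    for j in range(matrix.n):
        col = matrix.entries[:, j]
        col = col[col != GAP]
        if len(col) == 0:
            continue
        counts = np.bincount(col, minlength=len(matrix.site_alleles[j]))
        minor = counts.sum() - counts.max()
        if minor >= min_minor_count and minor / counts.sum() >= min_minor_fraction:
            out.append(j)
    return out


def select_reads(
    matrix: AlignmentMatrix,
    max_cov: int = 15,
    het_sites: Sequence[int] | None = None,
) -> AlignmentMatrix:
    """Subset of reads whose maximum coverage is at most ``max_cov``.

    A read's score is (number of covered het candidate sites, mean weight);
    reads are added best-first while every column they are active at stays
    under the cap.  A repair pass re-covers columns that would otherwise
    lose all their reads, evicting the lowest-scoring surplus reads where
    that is possible without uncovering another column.
    """
    if max_cov < 2:
        raise ValueError("max_cov must be >= 2")
    if matrix.max_coverage() <= max_cov:
        return matrix
    het = set(het_sites if het_sites is not None else candidate_het_columns(matrix))
    scores = []
    for i in range(matrix.m):
        nongap = matrix.entries[i] != GAP
        cov_cols = np.flatnonzero(nongap)
        n_het = sum(1 for j in cov_cols if j in het)
        mean_w = float(matrix.weights[i, nongap].mean())
        scores.append((n_het, mean_w))
    order = sorted(
        range(matrix.m),
        key=lambda i: (-scores[i][0], -scores[i][1], matrix.read_ids[i]),
    )
    depth = np.zeros(matrix.n, dtype=int)
    selected: list[int] = []
    for i in order:
        span = np.arange(matrix.first_nongap(i), matrix.last_nongap(i) + 1)
        if np.all(depth[span] < max_cov):
            selected.append(i)
            depth[span] += 1
    # repair: make sure no covered column loses its last read
    chosen = set(selected)
    col_nongap = matrix.entries != GAP
    for j in range(matrix.n):
        if col_nongap[np.array(sorted(chosen)), j].any():
            continue
        cands = [i for i in order if col_nongap[i, j]]
        if not cands:
            continue
        i = cands[0]
        span = np.arange(matrix.first_nongap(i), matrix.last_nongap(i) + 1)
        depth[span] += 1
        chosen.add(i)
        # evict surplus reads from over-full columns when safely possible
        for jj in np.flatnonzero(depth > max_cov):
            for cand in reversed(order):
                if cand not in chosen or cand == i:
                    continue
                if not (matrix.first_nongap(cand) <= jj <= matrix.last_nongap(cand)):
                    continue
                remaining = chosen - {cand}
                rem_idx = np.array(sorted(remaining))
                if col_nongap[rem_idx][:, col_nongap[cand]].any(axis=0).all():
                    chosen.remove(cand)
                    s2 = np.arange(
                        matrix.first_nongap(cand), matrix.last_nongap(cand) + 1
                    )
                    depth[s2] -= 1
                    if depth[jj] <= max_cov:
                        break
        if (depth > max_cov).any():
            # cannot repair without breaking the cap; leave the column bare
            chosen.remove(i)
            depth[span] -= 1
    return matrix.take_rows(chosen)
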