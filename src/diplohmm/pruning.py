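"""Greedy pruning and merging of bipartition HMMs for high coverage.

The exact HMM has 2^coverage bipartition states per column.  To stay
tractable beyond a row-count threshold t, the read set is split in two,
pruned HMMs are built recursively for the halves, low-probability states
are discarded (parameter v), and the halves are merged: a merged column's
bipartitions are all part-wise unions of one surviving bipartition from
each half, so its state count is the product of the two inputs' counts.

Pruning removes a bipartition when its column-local forward probability
(computed on the sub-HMM alone) falls below v times the column maximum;
the maximum state always survives and connectivity is repaired so the
result remains a usable sub-HMM of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hmm import (
    DiplotypeHMM,
    HMMColumn,
    ModelCache,
    build_hmm,
    forward_backward,
    restrict_masks,
)
from .matrix import AlignmentMatrix
from .substitution import SubstitutionModel


@dataclass
class PruneConfig:
    t: int = 8       # split threshold on the number of rows
    v: float = 0.01  # relative pruning threshold

    def __post_init__(self) -> None:
        if self.t < 2:
            raise ValueError("t must be >= 2")
        if not 0 <= self.v < 1:
            raise ValueError("v must be in [0, 1)")


def _split_rows(matrix: AlignmentMatrix, rows: Sequence[int]):
    """Interleave rows by start position so both halves span all columns."""
    ordered = sorted(rows, key=lambda i: (matrix.first_nongap(i), i))
    return tuple(ordered[0::2]), tuple(ordered[1::2])


def prune_hmm(hmm: DiplotypeHMM, v: float) -> DiplotypeHMM:
    """Drop bipartitions with column-local forward probability < v * max.

    After score pruning, a forward sweep repairs connectivity (if no
    surviving state of a column extends a surviving silent state of the
    previous column, the best-scoring such extension is re-added) and a
    backward sweep removes states with no surviving successor.  The result
    is connected: every state lies on a start-to-end path, provided the
    input HMM had that property (exact and merged HMMs do).
    """
    if v <= 0:
        return hmm
    tables = forward_backward(hmm)
    scores = [tables.alphas[j].sum(axis=1) for j in range(hmm.n)]
    keeps = [s >= v * s.max() for s in scores]
    # forward sweep: every kept state must extend a kept previous state
    for j in range(1, hmm.n):
        prev, col = hmm.columns[j - 1], hmm.columns[j]
        shared = np.intersect1d(prev.active, col.active)
        prev_keys = np.unique(
            restrict_masks(prev.bparts[keeps[j - 1]], prev.active, shared)
        )
        cur_keys = restrict_masks(col.bparts, col.active, shared)
        compatible = np.isin(cur_keys, prev_keys)
        if not (keeps[j] & compatible).any():
            cand = np.flatnonzero(compatible)
            keeps[j][cand[np.argmax(scores[j][cand])]] = True
        keeps[j] &= compatible
    # backward sweep: every kept state must have a kept successor
    for j in range(hmm.n - 2, -1, -1):
        col, nxt = hmm.columns[j], hmm.columns[j + 1]
        shared = np.intersect1d(col.active, nxt.active)
        next_keys = np.unique(
            restrict_masks(nxt.bparts[keeps[j + 1]], nxt.active, shared)
        )
        cur_keys = restrict_masks(col.bparts, col.active, shared)
        keeps[j] &= np.isin(cur_keys, next_keys)
    columns = [
        HMMColumn(
            active=col.active,
            bparts=col.bparts[keeps[j]],
            trans=col.trans,
            sigma=col.sigma,
        )
        for j, col in enumerate(hmm.columns)
    ]
    return DiplotypeHMM(hmm.matrix, hmm.model, hmm.rows, columns, hmm.cache)


def merge_hmms(h1: DiplotypeHMM, h2: DiplotypeHMM) -> DiplotypeHMM:
    """Join two HMMs over disjoint read sets into one over their union.

    For each column, every pair of bipartitions (one per input) is combined
    by part-wise union, giving |B_j^1| x |B_j^2| merged bipartitions.
    Transitions and emissions are recomputed on the merged states.
    """
    if h1.n != h2.n:
        raise ValueError("HMMs must have the same number of columns")
    if set(h1.rows) & set(h2.rows):
        raise ValueError("HMMs must cover disjoint read sets")
    if h1.matrix is not h2.matrix:
        raise ValueError("HMMs must reference the same alignment matrix")
    columns: list[HMMColumn] = []
    for j in range(h1.n):
        c1, c2 = h1.columns[j], h2.columns[j]
        active = np.union1d(c1.active, c2.active)
        pos = {int(r): k for k, r in enumerate(active)}
        shift1 = np.array([pos[int(r)] for r in c1.active], dtype=np.int64)
        shift2 = np.array([pos[int(r)] for r in c2.active], dtype=np.int64)

        def scatter(masks: np.ndarray, shifts: np.ndarray) -> np.ndarray:
            out = np.zeros(len(masks), dtype=np.int64)
            for k, sk in enumerate(shifts):
                out |= ((masks >> k) & 1) << int(sk)
            return out

        m1 = scatter(c1.bparts, shift1)
        m2 = scatter(c2.bparts, shift2)
        merged = (m1[:, None] | m2[None, :]).reshape(-1)
        columns.append(
            HMMColumn(active=active, bparts=merged, trans=c1.trans, sigma=c1.sigma)
        )
    rows = tuple(sorted(set(h1.rows) | set(h2.rows)))
    return DiplotypeHMM(h1.matrix, h1.model, rows, columns, h1.cache or h2.cache)


def compute_pruned_hmm(
    matrix: AlignmentMatrix,
    cfg: PruneConfig,
    model: SubstitutionModel,
    priors: Sequence[Mapping | None] | None = None,
    rows: Sequence[int] | None = None,
    cache: ModelCache | None = None,
) -> DiplotypeHMM:
    """Recursive pruned HMM construction (the scalable entry point).

    With at most ``cfg.t`` rows the exact HMM is returned; otherwise the
    rows are split in two by start position, pruned HMMs are computed
    recursively, pruned with threshold ``cfg.v`` and merged.
    """
    rows = tuple(range(matrix.m)) if rows is None else tuple(sorted(rows))
    cache = cache or ModelCache(matrix, model, priors)
    if len(rows) <= cfg.t:
        return build_hmm(
            matrix, model, priors, exact_cap=max(cfg.t, 1), rows=rows, cache=cache
        )
    rows1, rows2 = _split_rows(matrix, rows)
    if not rows1 or not rows2:  # degenerate split
        return build_hmm(
            matrix, model, priors, exact_cap=len(rows), rows=rows, cache=cache
        )
    h1 = compute_pruned_hmm(matrix, cfg, model, priors, rows1, cache)
    h2 = compute_pruned_hmm(matrix, cfg, model, priors, rows2, cache)
    return merge_hmms(prune_hmm(h1, cfg.v), prune_hmm(h2, cfg.v))
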