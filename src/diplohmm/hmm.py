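"""Diplotyping hidden Markov model and forward-backward inference.

Hidden states at column j are pairs (bipartition of the active reads,
ordered allele assignment (a1, a2)): reads in part 1 are explained by a
haplotype carrying a1, reads in part 2 by a2.  Between columns, silent
states over the active non-terminal reads enforce that a read never
switches haplotype.  Transitions into a column's states carry
P(a1, a2) = sum_Z P(a1|Z) P(a2|Z) P(Z), optionally reweighted by per-site
genotype priors.  Emissions multiply per-read allele likelihoods.

The forward-backward algorithm yields per-site genotype posteriors
(marginalizing over all read bipartitions), maximum-posterior genotypes,
haplotype sequences and a consistent read bipartition.

Bipartitions are encoded as bitmasks over the sorted active-row list
(bit k set = read active[k] in part 2), which keeps the dynamic program
fully vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import AlignmentMatrix
from .substitution import SubstitutionModel

Genotype = tuple[int, ...]  # sorted allele indices, e.g. (0, 1)


class CoverageCapError(RuntimeError):
    """Raised when exact state enumeration would be intractable."""


@dataclass
class HMMColumn:
    """States of one column: allowed bipartitions x allele pairs."""

    active: np.ndarray          # sorted global row indices active here
    bparts: np.ndarray          # allowed bipartition masks over `active`
    trans: np.ndarray           # (P,) transition probability per allele pair
    sigma: tuple[str, ...]

    @property
    def n_alleles(self) -> int:
        return len(self.sigma)

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.n_alleles
        p = np.arange(s * s)
        return p // s, p % s


@dataclass
class DiplotypeHMM:
    matrix: AlignmentMatrix
    model: SubstitutionModel
    rows: tuple[int, ...]               # global row indices the HMM covers
    columns: list[HMMColumn]
    cache: "ModelCache | None" = None

    @property
    def n(self) -> int:
        return len(self.columns)

    def state_counts(self) -> list[int]:
        """Per-column number of bipartition states."""
        return [len(c.bparts) for c in self.columns]


@dataclass
class ForwardBackwardTables:
    alphas: list[np.ndarray]    # per column (nb, P), scaled
    betas: list[np.ndarray]
    scales: np.ndarray          # per-column scaling constants
    log_likelihood: float

    def posterior(self, j: int) -> np.ndarray:
        post = self.alphas[j] * self.betas[j]
        return post / post.sum()


@dataclass
class GenotypeLikelihoods:
    posteriors: dict[Genotype, float]
    best: Genotype
    quality: float              # phred(1 - max posterior), capped


@dataclass
class Diplotype:
    hap1: np.ndarray            # allele index per site
    hap2: np.ndarray
    genotypes: list[Genotype]
    phase_sets: np.ndarray      # per-site phase-set label (block start position)
    het_mask: np.ndarray


@dataclass
class CallResult:
    diplotype: Diplotype
    likelihoods: list[GenotypeLikelihoods]
    assignments: dict[str, int]  # read_id -> haplotype 1 or 2
    log_likelihood: float
    matrix: AlignmentMatrix      # the (possibly selected) matrix actually used


@dataclass
class CallConfig:
    """Knobs of the calling pipeline."""

    exact_cap: int = 12          # max active rows for exact state enumeration
    max_coverage: int = 15       # read-selection cap before HMM construction
    prune_t: int = 8             # row-count split threshold of the pruning recursion
    prune_v: float = 0.01        # prune states below v * column maximum
    use_priors: bool = False     # reweight transitions by pileup genotype priors
    prior_error_rate: float = 0.07
    min_span_reads: int = 1      # reads required to join adjacent het sites
    gq_cap: float = 99.0
    ml_haplotypes: bool = False  # haplotype alleles from the ML state of the
    #                              decoded bipartition instead of the called
    #                              genotype (used by error re-estimation)


# -- construction ----------------------------------------------------------

def _active_rows_of(matrix: AlignmentMatrix, rows: Sequence[int], j: int):
    first, last = matrix._first, matrix._last
    return np.array(
        sorted(i for i in rows if first[i] <= j <= last[i]), dtype=np.int64
    )


class ModelCache:
    """Per-column transition tables and log emission likelihoods, shared by
    every sub-HMM built over the same matrix/model/priors (the pruning
    recursion builds many)."""

    def __init__(self, matrix, model, priors=None):
        self.matrix = matrix
        self.model = model
        self.priors = priors
        self._trans: dict[int, np.ndarray] = {}
        self._log_like: dict[int, np.ndarray] = {}

    def trans(self, j: int) -> np.ndarray:
        if j not in self._trans:
            prior = self.priors[j] if self.priors is not None else None
            self._trans[j] = column_transitions(
                self.model, self.matrix.site_alleles[j], prior
            )
        return self._trans[j]

    def log_like(self, j: int) -> np.ndarray:
        if j not in self._log_like:
            self._log_like[j] = np.log(
                self.model.column_likelihoods(self.matrix, j)
            )
        return self._log_like[j]


def column_transitions(
    model: SubstitutionModel,
    sigma: tuple[str, ...],
    prior: Mapping[Genotype, float] | None = None,
) -> np.ndarray:
    """Flattened P(a1, a2) for a column, optionally genotype-prior weighted.

    A heterozygous prior mass is split equally between the two ordered
    states; the weighted table is renormalized per column.
    """
    s = len(sigma)
    table = model.pair_table(sigma).reshape(-1).copy()
    if prior is not None:
        w = np.empty(s * s)
        for p in range(s * s):
            a1, a2 = p // s, p % s
            g = tuple(sorted((a1, a2)))
            mass = prior.get(g, 0.0)
            w[p] = mass / 2.0 if a1 != a2 else mass
        table *= w
        if table.sum() <= 0:
            raise ValueError("genotype prior annihilates all allele pairs")
    return table / table.sum()


def build_hmm(
    matrix: AlignmentMatrix,
    model: SubstitutionModel,
    priors: Sequence[Mapping[Genotype, float] | None] | None = None,
    exact_cap: int = 12,
    rows: Sequence[int] | None = None,
    cache: ModelCache | None = None,
) -> DiplotypeHMM:
    """Exact HMM: every bipartition of the active rows is a state.

    Refuses instances whose coverage exceeds ``exact_cap`` (state count is
    2^coverage); use :func:`diplohmm.pruning.compute_pruned_hmm` for those.
    """
    rows = tuple(range(matrix.m)) if rows is None else tuple(sorted(rows))
    cache = cache or ModelCache(matrix, model, priors)
    columns = []
    for j in range(matrix.n):
        active = _active_rows_of(matrix, rows, j)
        if len(active) > exact_cap:
            raise CoverageCapError(
                f"{len(active)} active rows at column {j} exceed the exact "
                f"enumeration cap {exact_cap}; use compute_pruned_hmm "
                "(Algorithm computePrunedHMM) instead"
            )
        columns.append(
            HMMColumn(
                active=active,
                bparts=np.arange(1 << len(active), dtype=np.int64),
                trans=cache.trans(j),
                sigma=matrix.site_alleles[j],
            )
        )
    return DiplotypeHMM(matrix, model, rows, columns, cache)


# -- forward-backward ------------------------------------------------------

def restrict_masks(
    masks: np.ndarray, from_rows: np.ndarray, to_rows: np.ndarray
) -> np.ndarray:
    """Project bipartition masks over ``from_rows`` onto the subset ``to_rows``."""
    out = np.zeros(len(masks), dtype=np.int64)
    pos = np.searchsorted(from_rows, to_rows)
    for k in range(len(to_rows)):
        out |= ((masks >> int(pos[k])) & 1) << k
    return out


def column_log_emissions(hmm: DiplotypeHMM, j: int) -> np.ndarray:
    """(nb, P) log emission table for column j."""
    col = hmm.columns[j]
    a1, a2 = col.pair_indices()
    log_e = np.zeros((len(col.bparts), len(a1)))
    if len(col.active) == 0:
        return log_e
    if hmm.cache is not None:
        log_like = hmm.cache.log_like(j)[col.active]
    else:
        log_like = np.log(hmm.model.column_likelihoods(hmm.matrix, j)[col.active])
    for k in range(len(col.active)):
        bit = ((col.bparts >> k) & 1).astype(bool)[:, None]
        log_e += np.where(bit, log_like[k, a2][None, :], log_like[k, a1][None, :])
    return log_e


def _shared_rows(col_prev: HMMColumn, col_cur: HMMColumn) -> np.ndarray:
    # rows active in both columns = active non-terminal rows of the previous
    return np.intersect1d(col_prev.active, col_cur.active, assume_unique=True)


def forward_backward(hmm: DiplotypeHMM) -> ForwardBackwardTables:
    """Scaled forward-backward over the bipartition HMM.

    Silent between-column states are handled by grouping forward/backward
    mass over the shared-read restriction of each bipartition; they carry no
    emission.  Per-column scaling keeps the recursion in linear space; for
    every column sum(alpha * beta) equals 1 after scaling.
    """
    n = hmm.n
    emissions = [np.exp(column_log_emissions(hmm, j)) for j in range(n)]
    alphas: list[np.ndarray] = []
    scales = np.empty(n)
    for j, col in enumerate(hmm.columns):
        base = col.trans[None, :] * emissions[j]
        if j == 0:
            alpha = base.copy()
        else:
            prev = hmm.columns[j - 1]
            shared = _shared_rows(prev, col)
            prev_keys = restrict_masks(prev.bparts, prev.active, shared)
            cur_keys = restrict_masks(col.bparts, col.active, shared)
            c_alpha = np.zeros(1 << len(shared))
            np.add.at(c_alpha, prev_keys, alphas[j - 1].sum(axis=1))
            alpha = c_alpha[cur_keys][:, None] * base
        s = alpha.sum()
        if not s > 0:
            raise FloatingPointError(
                f"zero total likelihood at column {j}: no state explains the data"
            )
        scales[j] = s
        alphas.append(alpha / s)
    betas: list[np.ndarray] = [np.empty(0)] * n
    betas[n - 1] = np.ones_like(alphas[n - 1])
    for j in range(n - 2, -1, -1):
        col, nxt = hmm.columns[j], hmm.columns[j + 1]
        shared = _shared_rows(col, nxt)
        contrib = (nxt.trans[None, :] * emissions[j + 1] * betas[j + 1]).sum(axis=1)
        next_keys = restrict_masks(nxt.bparts, nxt.active, shared)
        c_beta = np.zeros(1 << len(shared))
        np.add.at(c_beta, next_keys, contrib)
        cur_keys = restrict_masks(col.bparts, col.active, shared)
        beta = c_beta[cur_keys] / scales[j + 1]
        betas[j] = np.repeat(beta[:, None], alphas[j].shape[1], axis=1)
    return ForwardBackwardTables(
        alphas, betas, scales, float(np.log(scales).sum())
    )


# -- genotype posteriors ---------------------------------------------------

def genotype_posteriors(
    tables: ForwardBackwardTables, hmm: DiplotypeHMM, j: int, gq_cap: float = 99.0
) -> GenotypeLikelihoods:
    """Aggregate state posteriors of column j by unordered allele pair.

    Heterozygous genotypes collect both orderings (a1, a2) and (a2, a1).
    Ties in the arg-max break toward the genotype containing the reference
    allele (allele index 0), then lexicographically.
    """
    col = hmm.columns[j]
    post = tables.posterior(j)
    a1, a2 = col.pair_indices()
    agg: dict[Genotype, float] = {}
    for p in range(post.shape[1]):
        g = tuple(sorted((int(a1[p]), int(a2[p]))))
        agg[g] = agg.get(g, 0.0) + float(post[:, p].sum())
    best = min(agg, key=lambda g: (-agg[g], 0 not in g, g))
    err = max(1.0 - agg[best], 10.0 ** (-gq_cap / 10.0))
    quality = min(-10.0 * math.log10(err), gq_cap)
    return GenotypeLikelihoods(agg, best, quality)


# -- phase sets ------------------------------------------------------------

def assign_phase_sets(
    matrix: AlignmentMatrix,
    het_sites: Sequence[int],
    min_span_reads: int = 1,
) -> dict[int, int]:
    """Group heterozygous columns into phase sets.

    Adjacent het sites join one set iff at least ``min_span_reads`` reads
    span both (are active at both columns).  Each set is labelled by the
    reference position of its first site.
    """
    labels: dict[int, int] = {}
    current_label = None
    prev = None
    for j in sorted(het_sites):
        if prev is None:
            current_label = int(matrix.site_positions[j])
        else:
            spanning = matrix.active_rows(prev) & matrix.active_rows(j)
            if len(spanning) < min_span_reads:
                current_label = int(matrix.site_positions[j])
        labels[j] = current_label
        prev = j
    return labels


# -- full calling pipeline -------------------------------------------------

def _decode_bipartition(
    hmm: DiplotypeHMM, tables: ForwardBackwardTables
) -> tuple[dict[int, int], list[int]]:
    """Left-to-right constrained posterior decoding of the read bipartition.

    At each column the maximum-posterior bipartition consistent with the
    reads already assigned is chosen; newly active reads become fixed.  A
    read therefore keeps one haplotype for its whole length.  Returns the
    row -> part-bit map and the chosen bipartition index per column.
    """
    assigned: dict[int, int] = {}
    chosen: list[int] = []
    for j, col in enumerate(hmm.columns):
        post_b = tables.posterior(j).sum(axis=1)
        req_mask = 0
        req_bits = 0
        for k, r in enumerate(col.active):
            if int(r) in assigned:
                req_mask |= 1 << k
                req_bits |= assigned[int(r)] << k
        conflict = (col.bparts & req_mask) ^ req_bits
        ok = conflict == 0
        if ok.any():
            cand = np.flatnonzero(ok)
        else:  # pruned column without a fully consistent state: closest match
            counts = np.array([bin(int(c)).count("1") for c in conflict])
            cand = np.flatnonzero(counts == counts.min())
        bi = int(cand[np.argmax(post_b[cand])])
        b = int(col.bparts[bi])
        for k, r in enumerate(col.active):
            assigned.setdefault(int(r), (b >> k) & 1)
        chosen.append(bi)
    return assigned, chosen


def call_diplotype(
    matrix: AlignmentMatrix,
    model: SubstitutionModel,
    config: CallConfig | None = None,
) -> CallResult:
    """End-to-end diplotype call on an alignment matrix.

    Selects reads if coverage exceeds the configured cap, builds the exact
    HMM when tractable (otherwise the pruned/merged one), runs
    forward-backward, and reports per-site maximum-posterior genotypes,
    haplotypes, phase sets and a consistent read-to-haplotype assignment.
    """
    from .pruning import PruneConfig, compute_pruned_hmm
    from .selection import select_reads

    config = config or CallConfig()
    priors = None
    if config.use_priors:
        # priors come from all input reads, before any read selection
        from .alleles import column_genotype_priors

        priors = column_genotype_priors(matrix, config.prior_error_rate)
    if matrix.max_coverage() > config.max_coverage:
        matrix = select_reads(matrix, config.max_coverage)
    if matrix.max_coverage() <= config.exact_cap:
        hmm = build_hmm(matrix, model, priors, config.exact_cap)
    else:
        hmm = compute_pruned_hmm(
            matrix, PruneConfig(config.prune_t, config.prune_v), model, priors
        )
    tables = forward_backward(hmm)
    n = matrix.n
    likelihoods = [
        genotype_posteriors(tables, hmm, j, config.gq_cap) for j in range(n)
    ]
    genotypes = [gl.best for gl in likelihoods]
    het_mask = np.array([g[0] != g[-1] for g in genotypes])

    assigned, chosen = _decode_bipartition(hmm, tables)
    # canonical output labeling: lowest-indexed read goes to haplotype 1
    if assigned and assigned[min(assigned)] == 1:
        assigned = {r: 1 - b for r, b in assigned.items()}
        flip = True
    else:
        flip = False

    hap1 = np.empty(n, dtype=np.int16)
    hap2 = np.empty(n, dtype=np.int16)
    for j, col in enumerate(hmm.columns):
        s = col.n_alleles
        post = tables.posterior(j)
        bi = chosen[j]
        if config.ml_haplotypes:
            p = int(np.argmax(post[bi]))
            a1, a2 = p // s, p % s
        else:
            g = genotypes[j]
            g1, g2 = g[0], g[-1]
            if g1 == g2:
                hap1[j] = hap2[j] = g1
                continue
            p_fwd = post[bi, g1 * s + g2]
            p_rev = post[bi, g2 * s + g1]
            a1, a2 = (g1, g2) if p_fwd >= p_rev else (g2, g1)
        if flip:
            a1, a2 = a2, a1
        hap1[j], hap2[j] = a1, a2

    het_cols = [j for j in range(n) if het_mask[j]]
    labels = assign_phase_sets(matrix, het_cols, config.min_span_reads)
    phase_sets = np.empty(n, dtype=np.int64)
    current = labels[het_cols[0]] if het_cols else int(matrix.site_positions[0])
    for j in range(n):
        if j in labels:
            current = labels[j]
        phase_sets[j] = current

    assignments = {
        matrix.read_ids[r]: bit + 1 for r, bit in sorted(assigned.items())
    }
    diplo = Diplotype(hap1, hap2, genotypes, phase_sets, het_mask)
    return CallResult(diplo, likelihoods, assignments, tables.log_likelihood, matrix)
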