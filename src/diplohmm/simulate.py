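"""Synthetic diploid samples and long-read alignment matrices.

Simulation happens in *site space*: a read is a run of consecutive variant
columns copied from one of the two haplotypes, with independent allele
flips at the substitution error rate.  Indel errors are not modelled since
the analysis is restricted to SNVs.  Read spans are geometric with a
configurable mean (minimum one site) or fixed; read placement is uniform
with overhang beyond the matrix edges allowed, so expected depth is uniform
across columns.  All randomness is driven by the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import GAP, AlignmentMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_sites: int = 100
    het_fraction: float = 0.3
    coverage: float = 30.0
    read_length_sites: float = 5.0   # mean sites spanned per read
    substitution_error_rate: float = 0.05
    seed: int = 0
    fixed_span: bool = False         # use a constant span instead of geometric
    site_spacing: int = 50           # reference bp between adjacent sites

    def __post_init__(self) -> None:
        for rate in (self.het_fraction, self.substitution_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthData:
    """Ground-truth diplotype of a simulated sample."""

    positions: np.ndarray                 # reference coordinates (0-based)
    alleles: list[tuple[str, str]]        # (ref, alt) per site
    hap1: np.ndarray                      # allele index (0=ref, 1=alt) per site
    hap2: np.ndarray

    @property
    def genotypes(self) -> list[tuple[int, int]]:
        return [
            tuple(sorted((int(a), int(b)))) for a, b in zip(self.hap1, self.hap2)
        ]

    @property
    def het_mask(self) -> np.ndarray:
        return self.hap1 != self.hap2


def simulate_truth(cfg: SimulationConfig) -> TruthData:
    """Two haplotypes over ``n_sites`` bi-allelic sites.

    Each site is heterozygous with probability ``het_fraction`` (phase
    uniform); otherwise homozygous ref or alt with equal probability.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    positions = np.arange(n, dtype=np.int64) * cfg.site_spacing
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    alleles = [(str(_BASES[r]), str(_BASES[a])) for r, a in zip(ref, alt)]
    hap1 = np.zeros(n, dtype=np.int16)
    hap2 = np.zeros(n, dtype=np.int16)
    het = rng.random(n) < cfg.het_fraction
    phase = rng.integers(0, 2, size=n)
    hap1[het] = phase[het]
    hap2[het] = 1 - phase[het]
    hom_alt = ~het & (rng.random(n) < 0.5)
    hap1[hom_alt] = hap2[hom_alt] = 1
    return TruthData(positions, alleles, hap1, hap2)


def simulate_reads(
    truth: TruthData, cfg: SimulationConfig
) -> tuple[AlignmentMatrix, np.ndarray]:
    """Draw reads from the two haplotypes until the mean depth reaches
    ``cfg.coverage``; returns the matrix and per-read true haplotype labels
    (1 or 2).

    Entries are flipped to the other allele with the substitution error
    rate; entry weights are the phred score of that rate.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_sites
    err = cfg.substitution_error_rate
    weight = -10.0 * np.log10(err) if err > 0 else 60.0
    haps = (truth.hap1, truth.hap2)
    rows, weights_rows, ids, labels = [], [], [], []
    covered = 0
    target = cfg.coverage * n
    i = 0
    while covered < target:
        if cfg.fixed_span:
            span = max(int(round(cfg.read_length_sites)), 1)
        else:
            span = int(rng.geometric(1.0 / max(cfg.read_length_sites, 1.0)))
        start = int(rng.integers(-(span - 1), n))  # overhang keeps depth uniform
        lo, hi = max(start, 0), min(start + span, n)
        if hi <= lo:
            continue
        k = rng.integers(0, 2)
        row = np.full(n, GAP, dtype=np.int16)
        alleles = haps[k][lo:hi].copy()
        if err > 0:
            flip = rng.random(hi - lo) < err
            alleles = np.where(flip, 1 - alleles, alleles)
        row[lo:hi] = alleles
        w = np.zeros(n)
        w[lo:hi] = weight
        rows.append(row)
        weights_rows.append(w)
        ids.append(f"read{i}")
        labels.append(k + 1)
        covered += hi - lo
        i += 1
    # guarantee every column has coverage (vanishingly rare at normal depth)
    stacked = np.array(rows)
    for j in np.flatnonzero((stacked == GAP).all(axis=0)):
        k = rng.integers(0, 2)
        row = np.full(n, GAP, dtype=np.int16)
        row[j] = haps[k][j]
        w = np.zeros(n)
        w[j] = weight
        rows.append(row)
        weights_rows.append(w)
        ids.append(f"read{i}")
        labels.append(k + 1)
        i += 1
    matrix = AlignmentMatrix(
        np.array(rows),
        np.array(weights_rows),
        truth.positions,
        truth.alleles,
        ids,
    )
    return matrix, np.array(labels)


def simulate(cfg: SimulationConfig) -> tuple[TruthData, AlignmentMatrix, np.ndarray]:
    """Convenience wrapper: truth, matrix and read labels in one call."""
    truth = simulate_truth(cfg)
    matrix, labels = simulate_reads(truth, cfg)
    return truth, matrix, labels
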