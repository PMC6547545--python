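"""Probabilistic parameters of the diplotyping model.

Three ingredients:

* an ancestral allele prior P(Z_j) per column (flat by default),
* haplotype substitution probabilities P(H_j^k | Z_j) — a 4x4 nucleotide
  matrix, by default 0.1% per transversion and 0.4% per transition,
* a read error model P(M_ij | H_j^k), driven either by the per-entry phred
  weights of the alignment matrix (realignment-style) or by a single global
  substitution rate (re-estimated empirically, see
  :func:`reestimate_read_error`).

All probabilities are floored at 1e-6 and capped at 0.5 to keep the
log-domain finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .matrix import GAP, AlignmentMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .hmm import Diplotype

NUCLEOTIDES = ("A", "C", "G", "T")
PURINES = {"A", "G"}

ERROR_FLOOR = 1e-6
ERROR_CEIL = 0.5

DEFAULT_TRANSITION_RATE = 0.004  # purine<->purine / pyrimidine<->pyrimidine
DEFAULT_TRANSVERSION_RATE = 0.001


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in PURINES) == (b in PURINES))


def default_hap_substitution() -> np.ndarray:
    """4x4 P(H|Z): transitions 0.004, each transversion 0.001, diagonal rest."""
    q = np.zeros((4, 4))
    for zi, z in enumerate(NUCLEOTIDES):
        for ai, a in enumerate(NUCLEOTIDES):
            if a == z:
                continue
            q[zi, ai] = (
                DEFAULT_TRANSITION_RATE
                if is_transition(a, z)
                else DEFAULT_TRANSVERSION_RATE
            )
        q[zi, zi] = 1.0 - q[zi].sum()
    return q


def phred_to_error(weight: float) -> float:
    return float(np.clip(10.0 ** (-weight / 10.0), ERROR_FLOOR, ERROR_CEIL))


@dataclass
class SubstitutionModel:
    """Bundle of ancestral prior, haplotype substitution and read error model.

    ``use_weights`` selects the emission source: per-entry phred weights when
    available (taking precedence), else the scalar ``read_error_rate``.
    """

    hap_sub: np.ndarray = field(default_factory=default_hap_substitution)
    ancestral_prior: Mapping[str, float] | None = None  # None -> flat over Sigma_j
    read_error_rate: float = 0.01
    use_weights: bool = True

    def __post_init__(self) -> None:
        self.hap_sub = np.asarray(self.hap_sub, dtype=float)
        if self.hap_sub.shape != (4, 4):
            raise ValueError("hap_sub must be 4x4 over ACGT")
        if not np.allclose(self.hap_sub.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("hap_sub rows must sum to 1")

    # -- transition pair probabilities -----------------------------------
    def _prior_vector(self, sigma: tuple[str, ...]) -> np.ndarray:
        if self.ancestral_prior is None:
            return np.full(len(sigma), 1.0 / len(sigma))
        p = np.array([self.ancestral_prior.get(a, 0.0) for a in sigma], dtype=float)
        if p.sum() <= 0:
            raise ValueError("ancestral prior has no mass on the column alleles")
        return p / p.sum()

    def pair_table(self, sigma: tuple[str, ...]) -> np.ndarray:
        """|Sigma_j| x |Sigma_j| table of P(a1, a2) = sum_Z P(a1|Z)P(a2|Z)P(Z).

        The substitution rows are restricted to Sigma_j and renormalized so
        the table sums to exactly 1.
        """
        idx = [NUCLEOTIDES.index(a) for a in sigma]
        sub = self.hap_sub[np.ix_(idx, idx)]
        sub = sub / sub.sum(axis=1, keepdims=True)
        prior = self._prior_vector(sigma)
        # table[a1, a2] = sum_z prior[z] * sub[z, a1] * sub[z, a2]
        return np.einsum("z,za,zb->ab", prior, sub, sub)

    def transition_pair_probability(
        self, a1: str, a2: str, sigma: tuple[str, ...]
    ) -> float:
        if a1 not in sigma or a2 not in sigma:
            raise ValueError(f"allele outside column alphabet {sigma}")
        return float(self.pair_table(sigma)[sigma.index(a1), sigma.index(a2)])

    # -- emissions --------------------------------------------------------
    def error_probability(self, weight: float | None) -> float:
        if self.use_weights and weight is not None:
            return phred_to_error(weight)
        return float(np.clip(self.read_error_rate, ERROR_FLOOR, ERROR_CEIL))

    def emission_probability(
        self,
        observed: str,
        hap_allele: str,
        weight: float | None,
        sigma: tuple[str, ...],
    ) -> float:
        """P(observed | haplotype allele); gaps count as missing data (1.0)."""
        if observed == "-":
            return 1.0
        p_err = self.error_probability(weight)
        if observed == hap_allele:
            return 1.0 - p_err
        return p_err / max(len(sigma) - 1, 1)

    def column_likelihoods(self, matrix: AlignmentMatrix, j: int) -> np.ndarray:
        """(m, |Sigma_j|) array L[i, a] = P(M_ij | a); 1.0 at gaps.

        Vectorized emission table used by the forward-backward engine.
        """
        sigma = matrix.site_alleles[j]
        s = len(sigma)
        col = matrix.entries[:, j]
        if self.use_weights:
            p_err = np.clip(
                10.0 ** (-matrix.weights[:, j] / 10.0), ERROR_FLOOR, ERROR_CEIL
            )
        else:
            p_err = np.full(
                matrix.m, np.clip(self.read_error_rate, ERROR_FLOOR, ERROR_CEIL)
            )
        out = np.ones((matrix.m, s))
        nongap = col != GAP
        mis = p_err / max(s - 1, 1)
        for a in range(s):
            out[nongap, a] = np.where(
                col[nongap] == a, 1.0 - p_err[nongap], mis[nongap]
            )
        return out

    def with_error_rate(self, rate: float) -> "SubstitutionModel":
        return replace(self, read_error_rate=rate, use_weights=False)

    # -- flat config round-trip ------------------------------------------
    def to_config_text(self) -> str:
        """Serialize the model parameters as flat key=value lines."""
        lines = [
            f"read_error_rate={self.read_error_rate:g}",
            f"use_weights={int(self.use_weights)}",
        ]
        for zi, z in enumerate(NUCLEOTIDES):
            for ai, a in enumerate(NUCLEOTIDES):
                lines.append(f"hap_sub.{z}{a}={self.hap_sub[zi, ai]:.10g}")
        if self.ancestral_prior is not None:
            for a, p in sorted(self.ancestral_prior.items()):
                lines.append(f"ancestral_prior.{a}={p:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "SubstitutionModel":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = line.split("=", 1)
            kv[k] = v
        hap = default_hap_substitution()
        prior: dict[str, float] = {}
        for k, v in kv.items():
            if k.startswith("hap_sub."):
                z, a = k.split(".", 1)[1]
                hap[NUCLEOTIDES.index(z), NUCLEOTIDES.index(a)] = float(v)
            elif k.startswith("ancestral_prior."):
                prior[k.split(".", 1)[1]] = float(v)
        return cls(
            hap_sub=hap,
            ancestral_prior=prior or None,
            read_error_rate=float(kv.get("read_error_rate", 0.01)),
            use_weights=bool(int(kv.get("use_weights", 1))),
        )


# -- empirical re-estimation ----------------------------------------------

def reestimate_read_error(
    model: SubstitutionModel,
    matrix: AlignmentMatrix,
    haplotypes: "Diplotype",
    assignments: Mapping[str, int],
) -> SubstitutionModel:
    """One re-estimation step: set the global error rate to the empirical
    mismatch fraction between reads and their assigned haplotype.

    Returns the model unchanged when no reads are assigned.
    """
    mismatches = 0
    total = 0
    haps = (haplotypes.hap1, haplotypes.hap2)
    for i, rid in enumerate(matrix.read_ids):
        k = assignments.get(rid)
        if k not in (1, 2):
            continue
        row = matrix.entries[i]
        nongap = row != GAP
        total += int(nongap.sum())
        mismatches += int((row[nongap] != haps[k - 1][nongap]).sum())
    if total == 0:
        return model
    rate = max(mismatches / total, ERROR_FLOOR)
    return model.with_error_rate(rate)


def estimate_error_rate(
    matrix: AlignmentMatrix,
    start_rate: float = 0.01,
    max_iter: int = 10,
    tol: float = 1e-4,
    config=None,
) -> tuple[float, list[float]]:
    """Iterate diplotype calling and mismatch counting until the global read
    error rate stabilizes (movement < tol) or ``max_iter`` rounds.

    Starts from a flat ``start_rate`` substitution probability, calls a
    maximum-posterior bipartition and haplotype pair, re-estimates, repeats.
    Returns the final rate and the per-iteration history (including start).
    """
    from dataclasses import replace as _replace

    from .hmm import CallConfig, call_diplotype

    config = _replace(config or CallConfig(), ml_haplotypes=True)
    model = SubstitutionModel(read_error_rate=start_rate, use_weights=False)
    history = [start_rate]
    for _ in range(max_iter):
        result = call_diplotype(matrix, model, config)
        new_model = reestimate_read_error(
            model, matrix, result.diplotype, result.assignments
        )
        history.append(new_model.read_error_rate)
        if abs(new_model.read_error_rate - model.read_error_rate) < tol:
            model = new_model
            break
        model = new_model
    return model.read_error_rate, history
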