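"""Evaluation statistics and the read cutting/downsampling experiment.

Matching semantics are exact: a call is a true positive only when position,
alleles and genotype all agree with the truth set.  Genotype concordance is
computed over sites matched by position and alleles; switch errors are
counted within phase blocks over sites correctly genotyped as heterozygous
in both callsets, pooling adjacent-pair counts across blocks before
dividing (per-block rates are also available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import CallConfig, CallResult, call_diplotype
from .simulate import SimulationConfig, TruthData, simulate_reads, simulate_truth
from .substitution import SubstitutionModel

Genotype = tuple[str, ...]  # sorted allele strings


@dataclass(frozen=True)
class Call:
    """One variant call, enough for every metric here."""

    position: int
    ref: str
    alt: str
    genotype: Genotype                  # sorted allele strings
    hap_alleles: tuple[str, str] | None = None  # phased (hap1, hap2)
    phase_set: int | None = None


def calls_from_result(result: CallResult, truth_like=None) -> list[Call]:
    """Convert a :class:`CallResult` into the evaluation representation."""
    matrix = result.matrix
    out = []
    for j in range(matrix.n):
        sigma = matrix.site_alleles[j]
        d = result.diplotype
        g = tuple(sorted(sigma[a] for a in d.genotypes[j]))
        out.append(
            Call(
                position=int(matrix.site_positions[j]),
                ref=sigma[0],
                alt=sigma[1] if len(sigma) > 1 else sigma[0],
                genotype=g,
                hap_alleles=(sigma[d.hap1[j]], sigma[d.hap2[j]]),
                phase_set=int(d.phase_sets[j]),
            )
        )
    return out


def calls_from_truth(truth: TruthData) -> list[Call]:
    out = []
    for j in range(len(truth.positions)):
        ref, alt = truth.alleles[j]
        sigma = (ref, alt)
        g = tuple(sorted((sigma[truth.hap1[j]], sigma[truth.hap2[j]])))
        out.append(
            Call(
                position=int(truth.positions[j]),
                ref=ref,
                alt=alt,
                genotype=g,
                hap_alleles=(sigma[truth.hap1[j]], sigma[truth.hap2[j]]),
                phase_set=0,
            )
        )
    return out


def _by_position(calls: Sequence[Call]) -> dict[int, Call]:
    return {c.position: c for c in calls}


def genotype_concordance(calls: Sequence[Call], truth: Sequence[Call]) -> float:
    """Fraction of correct genotype predictions over sites matched by
    position and alleles.  NaN (with a warning) when nothing matches."""
    t = _by_position(truth)
    shared = [
        (c, t[c.position])
        for c in calls
        if c.position in t
        and {c.ref, c.alt} == {t[c.position].ref, t[c.position].alt}
    ]
    if not shared:
        warnings.warn("no sites shared between callset and truth")
        return float("nan")
    correct = sum(1 for c, tc in shared if c.genotype == tc.genotype)
    return correct / len(shared)


def precision_recall(
    calls: Sequence[Call], truth: Sequence[Call]
) -> tuple[float, float, float]:
    """(precision, recall, F1) under exact position+alleles+genotype matching."""
    if not calls or not truth:
        warnings.warn("empty callset")
        nan = float("nan")
        return nan, nan, nan
    t = _by_position(truth)
    tp = sum(
        1
        for c in calls
        if c.position in t
        and (c.ref, c.alt) == (t[c.position].ref, t[c.position].alt)
        and c.genotype == t[c.position].genotype
    )
    precision = tp / len(calls)
    recall = tp / len(truth)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def switch_error_rate(
    calls: Sequence[Call], truth: Sequence[Call]
) -> tuple[float, dict[int, float]]:
    """Pooled switch error rate and per-block rates.

    Evaluated over sites correctly genotyped as heterozygous in both sets,
    within each phase block; block boundaries never count as switches, and
    a global haplotype flip within a block costs nothing.
    """
    t = _by_position(truth)
    blocks: dict[int, list[tuple[int, int]]] = {}
    for c in sorted(calls, key=lambda c: c.position):
        tc = t.get(c.position)
        if tc is None or c.hap_alleles is None or tc.hap_alleles is None:
            continue
        if c.genotype != tc.genotype or c.genotype[0] == c.genotype[1]:
            continue
        orientation = 0 if c.hap_alleles == tc.hap_alleles else 1
        blocks.setdefault(c.phase_set or 0, []).append((c.position, orientation))
    switches = 0
    pairs = 0
    per_block: dict[int, float] = {}
    for ps, entries in blocks.items():
        orients = [o for _, o in entries]
        if len(orients) < 2:
            continue
        b_switch = sum(
            1 for a, b in zip(orients, orients[1:]) if a != b
        )
        b_pairs = len(orients) - 1
        switches += b_switch
        pairs += b_pairs
        per_block[ps] = b_switch / b_pairs
    if pairs == 0:
        warnings.warn("no evaluable adjacent heterozygous pairs")
        return float("nan"), per_block
    return switches / pairs, per_block


# -- cutting / downsampling experiment -------------------------------------

CUT_MODES = {"full": None, "cut2": 2, "cut1": 1}


def cutting_experiment(
    coverages: Sequence[float] = (10, 20, 25, 30),
    modes: Sequence[str] = ("full", "cut2", "cut1"),
    replicates: int = 50,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    call_config: CallConfig | None = None,
    model: SubstitutionModel | None = None,
) -> pd.DataFrame:
    """Mean genotyping error across a coverage x read-length grid.

    For every replicate one dataset is simulated at the base coverage, then
    downsampled to each target coverage and, per mode, reads are cut so that
    each fragment covers at most two variants ("cut2") or one ("cut1").
    Returns a tidy table with one row per (coverage, mode, replicate);
    aggregate with :func:`summarize_experiment`.

    The default calling configuration mirrors the re-genotyping workflow:
    per-site genotype priors are computed from all reads of the (possibly
    downsampled) dataset before read selection, so coverage beyond the
    selection cap still informs the calls.
    """
    base_config = base_config or SimulationConfig(
        n_sites=20, coverage=40.0, read_length_sites=5.0, seed=seed
    )
    call_config = call_config or CallConfig(use_priors=True)
    model = model or SubstitutionModel()
    records = []
    for rep in range(replicates):
        cfg_rep = SimulationConfig(
            **{**base_config.__dict__, "seed": seed + 1000 * rep}
        )
        truth = simulate_truth(cfg_rep)
        matrix_full, _ = simulate_reads(truth, cfg_rep)
        truth_calls = calls_from_truth(truth)
        for cov in coverages:
            sub = (
                matrix_full
                if cov == "full"
                else matrix_full.downsample(float(cov), seed=seed + 7 * rep + 1)
            )
            for mode in modes:
                k = CUT_MODES[mode]
                mat = sub if k is None else sub.cut_reads(k)
                result = call_diplotype(mat, model, call_config)
                conc = genotype_concordance(
                    calls_from_result(result), truth_calls
                )
                records.append(
                    {
                        "coverage": cov,
                        "mode": mode,
                        "replicate": rep,
                        "error": 1.0 - conc,
                    }
                )
    return pd.DataFrame.from_records(records)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean genotyping error per (coverage, mode)."""
    return (
        table.groupby(["coverage", "mode"], sort=False)["error"]
        .mean()
        .reset_index()
        .rename(columns={"error": "mean_error"})
    )
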