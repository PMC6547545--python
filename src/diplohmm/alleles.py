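"""Candidate SNV nomination and realignment-based allele detection.

Candidate sites come from a pileup over primary, mapping-quality-filtered
alignments: a position is nominated when the most frequent non-reference
base reaches a technology-specific frequency threshold (0.25 for PacBio,
0.4 for Nanopore) and is supported by at least 3 reads.

Each read's allele at a candidate site is decided by realigning the read
segment around the site against the reference window and against the
window with the alternative allele substituted in, under affine gap costs.
The cheaper alignment wins; the absolute cost difference becomes the
phred-scaled entry weight, and ties yield a gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .matrix import GAP, AlignmentMatrix

FREQUENCY_THRESHOLDS = {"pacbio": 0.25, "nanopore": 0.4}
MIN_ALT_READS = 3


@dataclass(frozen=True)
class CandidateSite:
    position: int            # 0-based reference coordinate
    ref: str
    alt: str
    alt_count: int
    alt_frequency: float

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele must differ from ref")
        if not 0.0 < self.alt_frequency <= 1.0:
            raise ValueError("alt frequency must be in (0, 1]")


@dataclass
class RealignmentParams:
    """Affine-gap costs, phred-scaled.  A length-L gap costs open + L*extend."""

    window_radius: int = 10
    gap_open: float = 30.0
    gap_extend: float = 10.0
    mismatch: float = 15.0

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.mismatch) <= 0:
            raise ValueError("all costs must be > 0")


def candidate_sites(
    pileup: Mapping[int, Mapping[str, int]],
    reference: Mapping[int, str],
    tech: str,
) -> list[CandidateSite]:
    """Nominate bi-allelic SNV candidates from per-position base counts.

    ``pileup`` maps position -> base -> read count; ``reference`` maps
    position -> reference base.
    """
    try:
        threshold = FREQUENCY_THRESHOLDS[tech.lower()]
    except KeyError:
        raise ValueError(
            f"unknown technology {tech!r}; expected one of "
            f"{sorted(FREQUENCY_THRESHOLDS)}"
        ) from None
    out = []
    for pos in sorted(pileup):
        counts = pileup[pos]
        ref = reference[pos].upper()
        total = sum(counts.values())
        if total == 0:
            continue
        nonref = {b: c for b, c in counts.items() if b.upper() != ref and c > 0}
        if not nonref:
            continue
        alt = max(sorted(nonref), key=lambda b: nonref[b])
        freq = nonref[alt] / total
        if nonref[alt] >= MIN_ALT_READS and freq >= threshold:
            out.append(CandidateSite(pos, ref, alt.upper(), nonref[alt], freq))
    return out


# -- realignment -----------------------------------------------------------

def _aligner(params: RealignmentParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 0.0
    a.mismatch_score = -params.mismatch
    a.open_gap_score = -(params.gap_open + params.gap_extend)
    a.extend_gap_score = -params.gap_extend
    return a


def realign_allele(
    read_segment: str,
    ref_window: str,
    alt_window: str,
    params: RealignmentParams | None = None,
) -> tuple[str | None, float]:
    """Decide which allele a read segment supports.

    Returns ``(allele, weight)`` where allele is ``"ref"``, ``"alt"`` or
    ``None`` (a gap entry, on cost ties or empty segments) and weight is
    the absolute difference of the two alignment costs.
    """
    if not read_segment:
        return None, 0.0
    params = params or RealignmentParams()
    aligner = _aligner(params)
    cost_ref = -aligner.score(ref_window, read_segment)
    cost_alt = -aligner.score(alt_window, read_segment)
    if cost_ref == cost_alt:
        return None, 0.0
    if cost_ref < cost_alt:
        return "ref", abs(cost_alt - cost_ref)
    return "alt", abs(cost_alt - cost_ref)


# -- genotype priors -------------------------------------------------------

def genotype_priors(
    ref_count: int, alt_count: int, error_rate: float
) -> dict[tuple[int, int], float]:
    """Prior over {hom-ref, het, hom-alt} from a site's allele counts.

    Binomial-mixture likelihood: under a genotype with alt-allele fraction
    f in {0, 1/2, 1}, each read observes the alt allele with probability
    f(1-e) + (1-f)e.  Returned normalized, keyed by genotype as sorted
    allele-index pairs.  Zero coverage yields a flat prior.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be >= 0")
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    keys = [(0, 0), (0, 1), (1, 1)]
    if ref_count + alt_count == 0:
        return {k: 1.0 / 3.0 for k in keys}
    logp = {}
    for key, f in zip(keys, (0.0, 0.5, 1.0)):
        p_alt = f * (1 - error_rate) + (1 - f) * error_rate
        logp[key] = alt_count * math.log(p_alt) + ref_count * math.log(1 - p_alt)
    mx = max(logp.values())
    raw = {k: math.exp(v - mx) for k, v in logp.items()}
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


def column_genotype_priors(
    matrix: AlignmentMatrix, error_rate: float = 0.07
) -> list[dict[tuple[int, int], float]]:
    """Per-column genotype priors from the matrix's own allele counts
    (bi-allelic columns; multi-allelic columns get a flat prior)."""
    priors = []
    for j in range(matrix.n):
        col = matrix.entries[:, j]
        col = col[col != GAP]
        if len(matrix.site_alleles[j]) != 2:
            sigma = matrix.site_alleles[j]
            keys = [
                (a, b) for a in range(len(sigma)) for b in range(a, len(sigma))
            ]
            priors.append({k: 1.0 / len(keys) for k in keys})
            continue
        priors.append(
            genotype_priors(int((col == 0).sum()), int((col == 1).sum()), error_rate)
        )
    return priors


def expected_nonref_filter(
    per_read_ref_posteriors: Mapping[int, Sequence[float]],
    min_expected: float = 3.0,
) -> list[int]:
    """Keep sites whose expected non-reference allele count exceeds the
    threshold (strictly greater).

    ``per_read_ref_posteriors`` maps site -> per-read P(reference allele).
    """
    return [
        site
        for site, ref_probs in sorted(per_read_ref_posteriors.items())
        if sum(1.0 - p for p in ref_probs) > min_expected
    ]


# -- pileup and matrix construction from alignments ------------------------

def pileup_from_alignments(
    alignment_path: str,
    min_mapping_quality: int = 30,
) -> dict[int, dict[str, int]]:
    """Per-position base counts over primary alignments with MQ >= threshold.

    Computed directly from the aligned pairs of each record (no external
    pileup tool).  Positions are 0-based reference coordinates.
    """
    import pysam

    counts: dict[int, dict[str, int]] = {}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for rec in af:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality < min_mapping_quality
            ):
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base == "N":
                    continue
                counts.setdefault(rpos, {}).setdefault(base, 0)
                counts[rpos][base] += 1
    return counts


def matrix_from_alignments(
    alignment_path: str,
    reference: Mapping[int, str] | str,
    sites: Iterable[CandidateSite],
    params: RealignmentParams | None = None,
    min_mapping_quality: int = 30,
) -> AlignmentMatrix:
    """Build an alignment matrix for candidate sites via realignment.

    ``reference`` is either a full reference string (indexed by position)
    or a mapping position -> base covering the realignment windows.
    """
    import pysam

    params = params or RealignmentParams()
    sites = sorted(sites, key=lambda s: s.position)
    if not sites:
        raise ValueError("no candidate sites supplied")

    def ref_base(p: int) -> str:
        return reference[p]

    def window(site: CandidateSite, alt: bool) -> str:
        r = params.window_radius
        left = "".join(
            ref_base(p) for p in range(max(site.position - r, 0), site.position)
        )
        mid = site.alt if alt else site.ref
        right = []
        for p in range(site.position + 1, site.position + r + 1):
            try:
                right.append(ref_base(p))
            except (IndexError, KeyError):
                break
        return left + mid + "".join(right)

    positions = [s.position for s in sites]
    site_alleles = [(s.ref, s.alt) for s in sites]
    rows, weights, ids = [], [], []
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for rec in af:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality < min_mapping_quality
                or rec.query_sequence is None
            ):
                continue
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            q_by_r = {r: q for q, r in pairs}
            row = np.full(len(sites), GAP, dtype=np.int16)
            wrow = np.zeros(len(sites))
            for k, site in enumerate(sites):
                if not rec.reference_start <= site.position < rec.reference_end:
                    continue
                rad = params.window_radius
                qpos_in = sorted(
                    q
                    for r, q in q_by_r.items()
                    if site.position - rad <= r <= site.position + rad
                )
                if not qpos_in:
                    continue
                segment = rec.query_sequence[qpos_in[0] : qpos_in[-1] + 1].upper()
                allele, w = realign_allele(
                    segment, window(site, False), window(site, True), params
                )
                if allele is None:
                    continue
                row[k] = 0 if allele == "ref" else 1
                wrow[k] = w
            if (row != GAP).any():
                rows.append(row)
                weights.append(wrow)
                ids.append(rec.query_name)
    if not rows:
        raise ValueError("no reads cover the candidate sites")
    stacked = np.array(rows)
    covered = (stacked != GAP).any(axis=0)
    keep = np.flatnonzero(covered)
    return AlignmentMatrix(
        stacked[:, keep],
        np.array(weights)[:, keep],
        [positions[k] for k in keep],
        [site_alleles[k] for k in keep],
        ids,
    )
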