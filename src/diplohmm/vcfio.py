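"""VCF input/output for diplotype calls (via pysam).

Output carries GT (phased with ``|`` inside a phase set), GQ, PS and
GL-style log10 genotype likelihoods.  Input VCFs provide candidate sites
for re-genotyping or phased truth sets for evaluation.
"""

from __future__ import annotations

import math

import pysam

from .evaluate import Call
from .hmm import CallResult


def write_vcf(
    result: CallResult,
    path: str,
    contig: str = "ref",
    sample: str = "sample",
    contig_length: int = 10_000_000,
) -> None:
    """Write the calls of a :class:`CallResult` as a single-sample VCF.

    Positions are converted from the 0-based internal convention to the
    1-based VCF convention.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    header.add_line(
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">'
    )
    header.add_line(
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description='
        '"Log10 genotype likelihoods (ref/ref, ref/alt, alt/alt)">'
    )
    header.add_sample(sample)
    matrix = result.matrix
    with pysam.VariantFile(path, "w", header=header) as vf:
        for j in range(matrix.n):
            sigma = matrix.site_alleles[j]
            d = result.diplotype
            rec = vf.new_record(
                contig=contig,
                start=int(matrix.site_positions[j]),
                alleles=(sigma[0], *sigma[1:]) if len(sigma) > 1 else (sigma[0], "."),
            )
            gl = result.likelihoods[j]
            het = bool(d.het_mask[j])
            phased = het  # within its phase set; hom genotypes are unphased
            rec.samples[sample]["GT"] = (int(d.hap1[j]), int(d.hap2[j]))
            rec.samples[sample].phased = phased
            rec.samples[sample]["GQ"] = int(round(gl.quality))
            rec.samples[sample]["PS"] = int(d.phase_sets[j]) + 1
            if len(sigma) == 2:
                order = [(0, 0), (0, 1), (1, 1)]
                rec.samples[sample]["GL"] = [
                    math.log10(max(gl.posteriors.get(g, 0.0), 1e-99))
                    for g in order
                ]
            vf.write(rec)


def read_calls(path: str) -> list[Call]:
    """Read a single-sample VCF into the evaluation representation."""
    out = []
    with pysam.VariantFile(path) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            s = rec.samples[sample]
            gt = s.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            alleles = rec.alleles
            hap = tuple(alleles[a] for a in gt)
            ps = s.get("PS")
            out.append(
                Call(
                    position=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else rec.ref,
                    genotype=tuple(sorted(hap)),
                    hap_alleles=hap if len(hap) == 2 else None,
                    phase_set=int(ps) if ps is not None else 0,
                )
            )
    return out


def read_candidate_positions(path: str) -> list[tuple[int, str, str]]:
    """(0-based position, ref, alt) triples from a candidate VCF."""
    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts:
                out.append((rec.start, rec.ref, rec.alts[0]))
    return out


def write_candidate_vcf(
    sites, path: str, contig: str = "ref", contig_length: int = 10_000_000
) -> None:
    """Minimal candidate-site VCF (CHROM, POS, REF, ALT)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for site in sites:
            rec = vf.new_record(
                contig=contig,
                start=site.position,
                alleles=(site.ref, site.alt),
            )
            vf.write(rec)
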