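# Methods

## Model

`diplohmm` treats diploid SNV genotyping as joint inference of a read
bipartition and a pair of haplotypes.  Reads are rows of an alignment
matrix M over candidate sites; the generative model assumes sites are
independent given the bipartition (an i.i.d.-across-sites assumption), an
ancestral allele Z_j per site drawn from a prior (flat over the column's
allele set by default), haplotype alleles drawn from Z_j through a
nucleotide substitution matrix, and read entries drawn from their
haplotype's allele through an error model.  Genotypes are the per-site
maximum-posterior unordered allele pairs after marginalizing over all
2^m read bipartitions.

The marginalization is organized as an HMM over matrix columns.  States
at column j are (bipartition of the active reads A_j) x (ordered allele
pair in Sigma_j^2); between columns, silent states over the reads active
and non-terminal at j tie consecutive columns together so that a read's
part assignment is constant over its whole length.  Transitions into a
column's states carry P(a1, a2) = sum_Z P(a1|Z) P(a2|Z) P(Z); all other
transition probabilities are 1 (out-degree-one structure).  Emissions
multiply per-read allele likelihoods; gap entries contribute factor 1
(missing data).

An exhaustive compatibility-graph construction
(`diplohmm.partition_graph`) mirrors the HMM without allele assignments.
Its start-to-end paths are in bijection with the 2^m ordered read
bipartitions, which the test suite exploits as an independent oracle: on
small instances, forward-backward must agree with brute-force summation
over the powerset of reads to 1e-9 (observed agreement is ~1e-15).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| haplotype substitution | 0.004 / 0.001 | per-site transition / transversion probability between ancestor and haplotype; diagonal is the remainder (0.994) |
| ancestral prior | flat | over the column's allele set |
| entry weights | phred | per-entry confidence; emission error = 10^(-w/10), clipped to [1e-6, 0.5] |
| global read error rate | 0.01 | used when weights are disabled (re-estimation mode) |
| exact enumeration cap | 12 active reads | above it the pruned construction is used |
| read selection cap | 15 | maximum per-column coverage fed to the HMM |
| prune split threshold t | 8 | sub-HMMs with at most t reads are built exactly |
| prune fraction v | 0.01 | drop bipartitions with column-local forward probability below v x column max |
| candidate thresholds | 0.25 (PacBio) / 0.4 (Nanopore), >= 3 reads | non-reference frequency and absolute support for nomination |
| expected non-ref filter | > 3 | strictly-greater expected non-reference allele count |
| realignment costs | open 30, extend 10, mismatch 15 (phred); window radius 10 bp | affine-gap realignment for allele detection; a length-L gap costs open + L*extend |
| genotype prior error rate | 0.07 | per-read error in the binomial-mixture site prior |
| min_span_reads | 1 | reads spanning adjacent het sites needed to join one phase set |

The pair-transition table restricts the 4x4 substitution matrix to the
column's allele set and renormalizes each row, so the table sums to
exactly 1 over Sigma_j^2.  Error probabilities are floored at 1e-6 and
capped at 0.5 throughout to keep the log-domain finite; the floor is what
bounds how strongly a single discordant read can sway a call.

## Numerical choices

Forward-backward runs in scaled linear space with one scaling constant
per column; silent states are handled by grouping state mass over the
restriction of each bipartition to the reads shared with the adjacent
column (a dense array indexed by the restricted bitmask).  After scaling,
sum(alpha * beta) is exactly 1 in every column, which the tests assert to
1e-9.  Bipartitions are bitmasks over the sorted active-read list, so all
per-column work is vectorized; per-column log-emission tables and
transition vectors are cached and shared across the many sub-HMMs the
pruning recursion builds.

Genotype arg-max ties break toward the genotype containing the reference
allele, then lexicographically.  Genotype quality is phred(1 - max
posterior), capped at 99.

## Read bipartition decoding

The output bipartition is obtained by constrained posterior decoding: the
columns are scanned left to right, at each column the maximum-posterior
bipartition consistent with the parts already fixed for previously seen
reads is selected, and newly active reads become fixed.  Because only
compatible transitions exist, a read never switches parts.  Independent
per-column arg-maxes need not be mutually compatible — especially in
pruned HMMs — which is why the decoding is constrained; if a pruned
column retains no fully consistent state, the state with the fewest
disagreements on already-fixed reads is used and earlier assignments are
kept.  The final labeling is canonicalized so the lowest-indexed read
belongs to haplotype 1.  Haplotype alleles per site come from the called
genotype, oriented by the posterior of the two orderings given the
decoded bipartition; the error re-estimation loop instead takes the
maximum-likelihood allele pair given the decoded bipartition, so that a
rare mis-genotyped site does not inflate the mismatch count.

## Pruning and merging

Coverage above the selection cap, or read counts above t, trigger the
recursive construction: reads are sorted by start position and split into
interleaved halves (keeping both halves spread over all columns —
the split rule is not prescribed, this is our choice), sub-HMMs are
built recursively, pruned, and merged.  Pruning scores each bipartition
by its column-local forward probability on the sub-HMM alone and drops
those below v times the column maximum (the maximum always survives);
forward and backward connectivity sweeps then ensure every surviving
state lies on a start-to-end path.  Merging takes the cross product of
the two survivors lists per column (part-wise unions), so merged
per-column state counts are exactly the product of the inputs' counts.
Pruning by forward probability (rather than posterior or emission score)
is a documented choice isolated in one function; with v = 0 the
construction is exact, which the tests verify to 1e-9 up to 12 reads.
State counts here count bipartitions per column; the full emitting-state
count is that number times |Sigma_j|^2.

## Site genotype priors

A per-site prior over {hom-ref, het, hom-alt} can reweight the transition
probabilities (heterozygous mass split equally between the two ordered
states, then renormalized per column — the composition of the prior with
the ancestral marginal is multiplicative, a choice we document since it
is not prescribed).  The prior is a binomial mixture: under alt-allele
fraction f in {0, 1/2, 1} each read observes alt with probability
f(1-e) + (1-f)e.  Priors are computed from all reads covering a site
*before* read selection, so coverage beyond the selection cap still
informs calls.  The pure model (no site priors) is the library default:
site priors sharpen calls when counts are informative but can override
the read-linkage evidence at heterozygous sites with extreme allele-count
imbalance.  The cutting/downsampling experiment harness enables them by
default because it emulates the re-genotyping workflow, where they are
part of the method.

## Simulator

The simulator works in site space: a read is a run of consecutive variant
columns.  Sites are bi-allelic with distinct ref/alt bases; each site is
heterozygous with probability `het_fraction` (phase uniform), otherwise
hom-ref or hom-alt equally.  Reads choose a parent haplotype uniformly,
span a geometric number of sites (mean `read_length_sites`, minimum 1; a
fixed-span mode exists for baselines), start uniformly with overhang
beyond the matrix edges allowed so expected depth is uniform across
columns, and are drawn until the mean depth reaches `coverage`.  Entries
flip to the other allele independently at `substitution_error_rate`;
weights are the phred score of that rate.  Everything is deterministic
given the seed.

What the simulator does not emulate: indel errors (the analysis is
restricted to SNVs, and indels are excluded by design), context-dependent
(homopolymer) error rates, mapping errors and alignment uncertainty,
reference bias in allele detection, and multi-allelic sites.  Passing
tests on this generator therefore demonstrate correctness of the
inference machinery and the qualitative value of read linkage, not
calling accuracy on real PacBio/Nanopore data.

Because the parent haplotype is an independent coin flip per read, a
heterozygous site can by chance be covered by reads from only one
haplotype (probability 2^(1-depth) per site); such a site is
information-theoretically impossible to genotype as heterozygous, which
bounds attainable concordance slightly below 1 even with error-free
reads.

## Experiment harness

The cutting/downsampling experiment simulates one dataset per replicate
at a base coverage of 40x over 20 sites (mean read span 5 sites, 5%
substitution error), downsamples it to each target coverage with common
random numbers (so the per-coverage read sets are nested), optionally
cuts reads into fragments covering at most 2 or exactly 1 variant, calls
genotypes, and reports the mean genotyping error per (coverage, mode).
These problem sizes are the package's desk-scale study conditions; the
qualitative result — full-length reads dominate cut reads, and error
falls with coverage — is stable, while individual cell differences at
high coverage are of the order of one miscalled site.

## Limitations

* Pruning is heuristic; no optimality guarantee after states are dropped
  (by design).
* Phase sets join on read span counts only; no quality threshold on the
  joining reads.
* Re-genotyping assumes bi-allelic SNVs at nominated sites; the matrix
  and HMM are multi-allele-capable but nomination is bi-allelic.
* The read selection heuristic is greedy; when capacity conflicts cannot
  be repaired without uncovering a column, a column may keep fewer reads
  than the cap would allow.
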