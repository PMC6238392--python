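# Methods

`m6atriage` implements a transcript-coordinate analysis of how oxidative
stress redistributes N6-methyladenosine (m6A) on mRNA and how methylated
transcripts are triaged to stress granules (SGs). It covers three assays —
antibody-based m6A sequencing (IP vs input coverage), ribosome profiling,
and whole-SG transcript-level PAR-CLIP — plus the statistics connecting
them, and ships a synthetic-data generator that plants ground truth for
every stage.

## Coordinate model

All analysis happens in transcript space: a transcript is its spliced
sequence, tiled exactly by annotated 5'UTR, CDS and 3'UTR lengths.
Coordinates are 0-based and half-open everywhere (intervals, bins, peak
spans); U is read as T. Genome coordinates, splicing and isoform assembly
are out of scope; when a gene has several isoforms, the longest is selected
(ties broken by lexicographically smallest transcript ID).

## DRACH scanning

m6A is deposited on the central adenosine of the degenerate pentamer DRACH
(D = A/G/U, R = A/G, then A-C, H = U/A/C; 18 concrete pentamers). Because
the consensus is fully degenerate, scanning is exhaustive window matching
rather than a scored-motif search: every window either matches or it does
not, so p-value machinery would add nothing. Overlapping matches are all
reported. A motif's segment is assigned by the position of its methylatable
A (`start + 2`): the mark sits on that adenosine, so a junction-spanning
pentamer belongs to the segment of its A. This attribution rule for
junction-spanning motifs is our choice; no convention is established.

## m6A calling

Per transcript and condition:

1. **Replicate merge.** Replicate coverage is summed after a concordance
   gate of Pearson r² ≥ 0.9 on log1p per-transcript totals; a discordant
   pair refuses to merge rather than silently averaging.
2. **Exclusion.** Transcripts whose *raw* IP coverage never reaches
   `coverage_min = 15` reads are excluded. The threshold is applied to raw
   rather than mean-normalized coverage because a normalized threshold of
   15 would be dimensionally odd; this choice is a documented substitute
   for an unstated rule.
3. **Adjustment.** IP and input profiles are each divided by their own mean
   coverage (all-zero profiles stay zero), and the normalized input is
   subtracted from the normalized IP. Negative values are retained, not
   clipped.
4. **Peak calling.** Peaks are maximal runs of adjusted excess > τ = 0.5
   (normalized units) at least 10 nt wide. Both knobs are configurable; the
   rule is the simplest one whose recovery is verifiable against planted
   truth. No peak-calling rule is established for this adjustment scheme,
   so threshold-and-run is a deliberate design choice.
5. **Motif assignment.** Peaks covering no predicted DRACH motif are
   discarded; every motif whose pentamer intersects a retained peak is
   called methylated (deduplicated across overlapping peaks).

The per-transcript **m6A/A ratio** is called motifs over predicted motifs;
transcripts with zero predicted motifs are flagged and omitted from ratio
distributions. **Stress-induced sites** are motifs called under stress but
not control (gains only; losses are not "induced").

**Metagene profiles** pool motifs across transcripts into 10/30/10 bins
(5'UTR/CDS/3'UTR, configurable): bin b of a segment of length L covers
[⌊bL/n⌋, ⌊(b+1)L/n⌋), so bin sizes differ by at most 1 nt. The per-bin
value is pooled methylated over pooled predicted motifs; bins with no
predicted motifs are reported missing (NaN), not zero. A transcript with a
nonempty segment shorter than its bin count cannot be binned and is skipped
(direct over-binning of a single transcript is an error). The "5' vicinity
of the CDS" is operationalized as the first 20% of CDS bins.

## Translation classification

Ribosome density (RD) is RPF[RPM]/mRNA[RPM]. Because library-size
renormalization absorbs a global shift, RD is baselined by the
per-condition *median RD of mitochondrially encoded genes*, whose
expression and translation are insensitive to the cytosolic stress
response; the global repression then appears as the median per-gene
log2(RD_control/RD_stress) over genes detected in both conditions.

The translation ratio R_t measures initiation stalling over the first
100 nt of the CDS (window counted from the first CDS base and truncated to
the CDS). Two forms are provided:

* **FRACTION** (default): reads in the window over total CDS reads, in
  [0, 1]; library-size factors cancel.
* **LITERAL_RPKM**: (window reads per window kb)/(CDS reads per CDS kb) =
  FRACTION × (CDS length / window). Under this form a perfectly uniform
  gene scores exactly 1 — i.e. "stalled" at the 0.5 cutoff — contradicting
  the use of uniform RPF coverage as the signature of genuine translation.
  FRACTION is therefore the default; LITERAL_RPKM is retained for
  comparison.

Genes with R_t ≤ 0.5 are TRANSLATED, R_t > 0.5 STALLED, and genes without
RPF or mRNA signal UNDETECTED. The denominator uses CDS reads and the
window is 100 nt of CDS ("full gene" being ambiguous); both are
configurable. Start-aligned metagene densities normalize each gene's
profile to sum 1 over a [-50, +500) window around the CDS start and average
genes with equal weight, so highly expressed genes do not dominate.

## SG-client selection

Whole-SG PAR-CLIP is used purely at transcript level (no binding-site
analysis, no T→C conversion modelling). Replicates are merged after an r²
gate on log RPKM of co-detected transcripts; for PAR-CLIP the default gate
is 0.6 rather than 0.9, since SG-capture replicates are intrinsically
noisier than the sequencing libraries (the protocol this emulates reported
replicate r² near 0.7 and merged anyway). Enrichment is

log2(RPKM_stress + ε) − log2(RPKM_control + ε),

with ε defaulting to half the smallest nonzero RPKM across the pair, which
keeps control-absent transcripts defined and makes the statistic exactly
antisymmetric under condition swap. A transcript is an SG client when
detected in stress and enriched at or above the cutoff.

**Enrichment cutoff.** The emulated protocol is quotable two ways: "twofold
enrichment over control" and "a threshold of log2 = 2" (fourfold). The
package defaults to **log2 ≥ 1 (twofold)**. With clients at a true 4-fold
enrichment, a cutoff at exactly log2 = 2 sits at the centre of the client
noise distribution and can never recover more than about half of them —
whereas a twofold cutoff leaves the 4-fold effect a comfortable margin on
both sides. The fourfold reading is one config knob away
(`enrichment_log2_cutoff: 2.0`), and every run's summary records which
cutoff was applied.

Detection floors come from spike-ins of known concentration: the threshold
of a library is the minimum mean RPKM among spike-ins observed (nonzero) in
every replicate. The min-qualifying-spike-in rule is our construction; only
the fact that spike-ins set the threshold is given. The **SG metagene set**
is the union of PAR-CLIP clients and transcripts stalled in ribosome
profiling, each member tagged PARCLIP, STALLED or BOTH.

## Statistics

Rank-sum comparisons use the Mann-Whitney U test, two-sided by default
(sidedness is not specified in the emulated analysis), with midrank ties,
exact enumeration for pooled n ≤ 12 without ties, and otherwise the normal
approximation with tie and continuity corrections. Gene-set overlaps use
the upper-tail hypergeometric probability P(X ≥ k); the universe N must be
supplied explicitly and defaults in the pipeline to the analyzed
transcriptome of the run (the original universe is unstated). Pearson r is
reported with r². The numerics are delegated to scipy.stats; tests verify
them against independent enumeration oracles.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 2,000 transcripts
(13 mitochondrial, 20 spike-ins), lognormal segment lengths (median
150/900/500 nt for 5'UTR/CDS/3'UTR with hard minima 60/300/60 so every
transcript holds the default binning and the stall window), lognormal
expression with mean per-nucleotide input coverage 60× (floor 30×), 55% SG
clients, a 40% control methylation rate placed with 3'UTR-biased region
weights (0.1/0.2/0.7), stress-induced sites added to 70% of SG clients and
restricted to the 5'UTR plus first 20% of the CDS, 8-fold IP enrichment
over a triangular kernel of half-width 25 nt, Poisson (variance = mean)
integer count noise, 85% stall fraction within the first 100 CDS nt for
stalled genes, a planted global RD shift of log2 = 2.9 sparing
mitochondrial genes, and 4-fold PAR-CLIP client enrichment with 20% CV
lognormal noise in two replicates. Every nonempty segment is guaranteed at
least one DRACH motif by resampling. A fixed seed yields byte-identical
output files (all randomness flows through named SeedSequence children).

PAR-CLIP library sizes are depth-matched across conditions (the fixed
nominal control depth), emulating spike-in-calibrated sequencing depth.
Without this, within-library normalization would absorb most of the planted
fold (the stress library's total signal is ~2.6× the control's) and
cross-condition RPKM ratios would not report abundance folds — the
compositional problem spike-ins exist to solve.

Deliberately not modelled: read-level artifacts (FASTQ, alignment, PCR
duplicates), codon periodicity and A-site offsets, fragment-length effects
beyond the triangular kernel, sequence-dependent antibody affinity,
correlated noise between IP and input, mRNA degradation under stress, and
any coupling between methylation and expression level. Passing recovery
tests therefore show that the *inference rules* are correct and calibrated
under the stated noise model, not that the pipeline is robust to every
artifact of real libraries.

Recovery scoring matches calls to planted sites at peak resolution: a
called motif is a true positive when within one kernel half-width (25 nt)
of a planted site on the same transcript. The calling rule deliberately
marks every DRACH under a peak (fragment-level data cannot resolve single
bases), so base-exact identity with the single planted motif is not the
quantity recovery measures.

Note that under this generative model about 82% of SG clients end up
methylated under stress (1 − (1 − 0.4)(1 − 0.7)); the generator targets the
stress-induced gain fraction, not the composite methylated-client fraction.

## Numerical choices and degenerate inputs

* All-zero coverage normalizes to all zeros; zero-mRNA or zero-RPF
  transcripts are flagged UNDETECTED rather than dropped silently.
* Boundary conventions are inclusive where a statement reads "at least":
  R_t = 0.5 is TRANSLATED, detection at the spike-in floor counts, an
  enrichment exactly at the cutoff is a client, IP max exactly 15 is kept.
* Replicate merges and RD baselining fail loudly (refused merge, missing
  mitochondrial baseline) instead of degrading.
* Peak ties and plateaus need no tie-break: runs are maximal by
  construction and a peak's height is its maximum value.

## Problem sizes

The default study is 2,000 transcripts (~3.3 Mnt) with two replicates per
m6A library; a full generate-and-analyze cycle runs in well under a minute
on one CPU. The test suite uses a 150-transcript bundle for integration
tests and the full default study for end-to-end recovery checks.
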