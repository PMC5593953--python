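# Methods

## The model system

The package models a single complex transgene integration locus on one
chromosome: a short fragment of the cloning vector (517 b by default)
deposited at sub-site *Ins1*, a head-to-tail concatemer of full-length
vector copies at sub-site *Ins2* ~250 kb downstream of a two-gene cluster
(*Ins1* lies ~100 kb upstream of it), and three deletions of host
sequence associated with the integration, the largest (100 kb) removing a
non-expressed gene analog (`ak_analog`). The phenotype model is a
recessive trait with incomplete penetrance: only transgene homozygotes
express it, each with probability *p* (default 0.75).

All real-genome distances are multiplied by a `scale` parameter before
the architecture is realized, 0.05 by default, so the full topology fits
on a 500 kb contig and a complete simulate–map–call cycle runs in
seconds. Scaling preserves every qualitative feature the callers rely on
(junction structure, copy-number contrasts, deletion dosage); it reduces
the number of windows per deletion and the absolute evidence counts, so
recovery at scale is, if anything, harder than at full size.

## Synthetic data

**Reference and haplotypes.** The wild-type contig is uniform random DNA
(seeded); gene analogs are placed deterministically from the
architecture, so two seeds share coordinates but not sequence. The
transgenic haplotype is built by a single left-to-right pass that excises
each deletion and deposits the *Ins1* fragment and the concatemer,
recording every junction and a piecewise liftover map in a truth set.
The length identity
`|tg| = |wt| − Σ deletions + copies·|vector| + |ins1 fragment|`
is property-tested. For each insertion junction the truth set also stores
the micro-homology interval — how far the breakpoint can shift while
describing an identical haplotype because the insert's head or tail
coincidentally matches the flanking reference. Breakpoint errors are
measured as distance to that interval; positions inside it are
indistinguishable from the truth by any method, in principle.

**Reads.** Paired 150 b reads from fragments with Normal(550, 60) lengths
(truncated below at the read length), substitution errors only at a flat
rate (default 0.002), constant Q40 qualities. The substitution-only model
reflects a modern short-read library, where indel errors are an order of
magnitude rarer; it also justifies the mapper's ungapped extension.
Fragments are drawn in proportion to haplotype length (DNA mass), so a
heterozygote's longer, insertion-bearing haplotype contributes
proportionally more fragments and per-base coverage stays equal across
haplotypes — this matters for copy-number dosage. Read names carry truth
tags (`frag<N>:<hap>:<contig>:<start>:<end>:<strand>`) consumed only by
tests. One top-level seed derives all child seeds; identical config and
seed give byte-identical FASTQ.

**What the generator does not emulate.** GC and PCR bias, indels,
quality-score structure, repeats (the background is uniform random DNA, so
21-mers are essentially unique), chimeric library artifacts, and multiple
chromosomes. Passing tests therefore demonstrate correctness of the
inference chain under a clean error model, not robustness to real-genome
repeat structure — on real data the uniqueness filter would discard far
more reads.

**Colonies.** Each F2 offspring draws a genotype from Multinomial(¼, ½,
¼); homozygotes are affected with probability *p*. Counts are pooled the
way a presence/absence assay reports them: negatives, positive normals
(heterozygotes plus unaffected homozygotes), positive affected.

## Mapping

A sorted k-mer index (k = 21, forward strand) over all contigs including
`vector`; reads are queried in both orientations with seeds every 10
bases. Each seed hit votes for a diagonal; each candidate placement is
verified by ungapped extension — the maximum-scoring contiguous segment
(match +1, mismatch −3) found by a cumulative-sum Kadane scan — which
soft-clips read ends that cross a junction or contig end. A placement is
unique when no competing locus scores within a margin of 2; only unique
placements feed the callers, mirroring a uniquely-mapped-reads filter.
The batch path vectorizes seeding and accepts perfect full-length
placements directly (these are provably the extension optimum); every
other candidate goes through the same per-candidate extension, so batch
and per-read results are identical. An exhaustive all-positions scan
serves as an independent oracle in tests on ≤ 10 kb references.

Fragments are classified with precedence CHIMERIC_GENOME_VECTOR >
SPLIT_JUNCTION > GENOME_CONCORDANT > VECTOR_INTERNAL > DISCORDANT_GENOME
> UNMAPPED. Concordance requires opposite strands and an implied insert
within mean ± 4 sd. A soft-clip of ≥ 20 b that re-aligns uniquely to the
other contig class is a split observation; chimeric pairs are also
scanned for them so their junction-crossing mates still contribute
base-pair evidence.

## Insertion calling

Chimeric pairs contribute the genome mate's junction-proximal coordinate
(3' end of a `+` mate, start of a `−` mate); split reads contribute the
clip boundary. Evidence is clustered by single linkage with a 1100 b
window (~2 fragment lengths, the localization uncertainty of a chimeric
pair); clusters with ≥ 3 observations become calls. With split reads the
breakpoint is their modal coordinate (ties broken toward the smaller);
otherwise the interval between the innermost left- and right-side pair
coordinates is reported. The breakpoint convention is left-aligned: the
call coordinate is the first wild-type base after the junction's left
flank. Vector-internal pairs and concatemer wrap-around reads are never
reported as genomic calls; they only support the copy-number estimate.

## Depth, deletions, copy number

Depth is aligned-base count per 200 b window over uniquely mapped
records; normalization divides by the median of unmasked windows
(insertion-call flanks ± one insert length and one insert length at each
contig end are masked — junction and edge coverage ramps would otherwise
bias both the median and the caller).

Deletion calling scans for runs of ≥ 3 unmasked windows below the
heterozygous band's upper edge (0.7), merging runs separated by ≤ 3
near-qualifying "bridge" windows (< 0.85): at 30×, one interior window of
a true deletion occasionally fluctuates just above the band. A run's
zygosity comes from its mean (hom < 0.25, else het), and a run must sit
≥ 5 robust SDs (1.4826 × MAD of unmasked windows) below baseline.
Because a ~0.5× dip over a kilobase can arise from fragment-sampling
noise alone, heterozygous calls additionally require ≥ 2 discordant
pairs whose stretched inner gap brackets the run — the classic
orthogonal read-pair signal; homozygous calls (near-zero depth) need no
corroboration.

Edges are refined to base resolution. Reads crossing an excision junction
are soft-clipped exactly at the deletion edge, so alignment ends (left
edge) and starts (right edge) pile up on the breakpoint base, smeared ≤ 2
bases inward by chance-matching absorption; piles are aggregated over
that range. When spanning pairs exist, their innermost mate coordinates
already bracket the junction to within a few tens of bases, and the edge
is the strongest pile next to that bound (falling back to the bound). In
the depth-only regime the edge is the pile candidate minimizing a
two-level changepoint fit of per-base coverage, or the pure fit when no
pile exists.

Transgene dosage is `copies_per_diploid = 2 × (vector mean depth /
unmasked genome mean depth)`: ≈ n for a heterozygote with an n-copy
concatemer, ≈ 2n for a homozygote, plus a small fractional contribution
from the *Ins1* fragment over its interval. The marker-locus genotype is
`round(2 × mean normalized depth)` clamped to {0, 1, 2} and mapped to
HOM/HET/WT — a deliberately categorical readout matching a copy-number
assay's decision logic; no likelihood model is attempted.

## Transmission genetics

Uncorrected Pearson chi-square, with the upper-tail probability from the
regularized upper incomplete gamma function (`scipy.stats.chisquare`).
No continuity correction: the uncorrected statistic reproduces all four
published two-decimal p-values (0.28, 0.01, 0.77, 0.04), the corrected
one does not. The two packaged colony tables are shipped as printed, with
one count per colony left blank and reconstructed by the loader from the
published total (433 − 118 − 234 = 81 affected; 260 − 193 = 67
negatives); the reconstruction is an explicit, validated loader step.
Penetrance is the plug-in estimator (C/N)/(1/4), clamped to [0, 1] with a
flag; a Wilson-based interval is available as an extra diagnostic and is
not part of the published readout.

## Problem sizes and numerical choices

Simulation studies use the default conditions (500 kb contig, scale 0.05,
30×, error 0.002) for insertion and deletion recovery — 20 homozygote
runs plus wild-type negative controls, and 3 + 3 runs for deletions — and
a 150 kb contig at scale 0.02 for the 90-run genotyping sweep and the
error-free copy-number linearity sweep (1, 2, 5, 10 copies), the same
topology at 30 % of the sequencing volume. Statistical calibration uses
10,000 simulated colonies of 400 under a fully penetrant (true) 1:2:1
hypothesis. Ties in alignment ranking break by (contig, position, strand)
for determinism; cluster order is fixed by sorting evidence before
linkage; all randomness flows from one seed via `SeedSequence`.

## Known limitations

Ungapped alignment cannot represent indels in external SAM input; the
concatemer's internal structure (copy count beyond dosage, per-copy
orientation) is not resolved; deletion-edge refinement assumes sharp
excision junctions; the categorical 2/1/0 genotype saturates below ~0.25
and above ~0.75 normalized dosage; and none of the wet-lab readouts the
original study pairs with this analysis (expression, enzymology,
tonometry, histology) are in scope.
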