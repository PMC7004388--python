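# Methods

## Scope and model

`subtelomap` analyzes subtelomeric structural variation from nick-label
optical maps. The unit of data is the label map: an ordered integer
vector of label coordinates (bp) along a DNA segment, produced in
reality by nicking genomic DNA at a 7-bp recognition site (Nt.BspQI,
`GCTCTTC`, label reported at the motif start on the forward strand and
mirrored on the reverse), and in silico by scanning a reference sequence
on both strands. Coordinates are 0-based half-open throughout, and every
arm-local map is oriented so position increases toward the telomere
(p-arm windows are mirrored); this single convention makes extension
arithmetic identical for p and q arms.

A reference arm is the distal window of an arm (500 kb by default) with
its label map, N-gap intervals, the annotated arm end (`tel_end_bp`,
which includes any terminal run of Ns — the same convention reference
assemblies use for telomere-adjacent gap padding) and a 1-copy interval
marking arm-specific, non-duplicated DNA. Extensions are measured
against the annotated end, so a contig stopping short of an excess
N-gap yields a negative correction (the gap should shrink or be
deleted) and extra subtelomeric DNA yields a positive one; differences
below the 10-kb resolution are reported as 0, larger ones on a 5-kb
grid, the granularity at which such corrections are meaningfully
resolved.

## Alignment

Pairwise alignment of label maps uses the standard likelihood-style
scoring for restriction/nick maps: a matched chunk with query interval
`dq`, reference interval `dr` and `nq`/`nr` skipped labels scores

    reward − (dq − dr)² / (2·(cv²·dr² + 2·jitter²)) − nq·fp − nr·fn

The variance term combines multiplicative sizing error on the interval
(`cv = 0.02`) with additive position jitter at the two flanking labels
(`jitter = 300 bp`); `fp = fn = −ln(0.10)` mirror the labeling error
rates; `reward = 3.0` approximates the log-odds of a correct interval
match against a random spacing agreement. Dynamic programming with at
most 3 consecutive skipped labels per side per chunk yields the optimum;
two modes differ only in boundary treatment: *fit* (global in the
query, local in the target; boundary query labels pay `fp`) and
*dovetail* (for assembly; at each end the side with fewer outstanding
labels is treated as inside the overlap and pays per-label penalties,
the other side's overhang is free). The DP inner kernel is
numba-compiled; all scores are rounded to 1e-9 before comparisons, and
ties prefer the lower target offset, then '+' orientation, so runs are
bit-reproducible at a fixed seed.

Acceptance thresholds (`min_aligned_labels = 9`, `min_score = 12`) were
calibrated once against the random-map null (`estimate_null_scores`):
the best dovetail score between unrelated 28-label maps stays below
~10.5 (99th percentile ≈ 9), so the defaults keep the random-pair
false-discovery rate under 1% while admitting genuine minimum-length
(150-kb) overlaps at 10% label error, whose scores concentrate near
~17.

## Assembly

Assembly follows overlap-layout-consensus. Molecules shorter than
150 kb are excluded (the study design's length filter). All-vs-all
dovetail alignments above threshold become directed edges carrying the
placement offset; edges whose offsets fail to close around triangles
(tolerance 4× the 1.5-kb optical resolution) lose their weakest member,
cycles are broken at the weakest edge, and transitively redundant edges
are removed, leaving a DAG per component. Components of fewer than 3
molecules are reported as failed to assemble (a stand-in floor; the
minimum depth for calling a contig is not otherwise constrained). Per
component, the heaviest path (sum of edge scores, favouring deep
consistent overlaps over hop count) defines the layout; the draft
consensus clusters the path molecules' placed labels (cluster width =
optical resolution) and keeps clusters supported by at least
`max(2, 0.3 × local depth)` distinct molecules — with 10% scattered
false-positive labels, true labels sit near 90% support and the two
populations separate cleanly at 0.3.

Refinement then iterates to a fixed point (≤5 rounds; convergence =
no label added/removed and no move >100 bp): every molecule is
re-fit-aligned to the consensus and counted as placed when both its own
labels mostly match (≥65%) and the consensus labels inside its span are
mostly matched back (≥60%); consensus label positions are recomputed as
medians of the molecule labels *matched to them by the DP* — not by
re-clustering raw placements, which splits clusters once sizing-noise
random walks exceed the cluster width; labels closer than the optical
resolution are re-merged; and well-supported clusters of unmatched
labels hanging beyond either end extend the map. Interior insertion is
deliberately forbidden: interior unmatched labels are the signature of
a second haplotype, not a consensus defect.

Two further signals drive haplotype separation in diploid arms, and
their carriers are re-assembled in a second pass: (i) placed molecules
showing a run of ≥3 consecutive unmatched labels interior to the
consensus, and consensus regions whose label support drops toward 50%
of depth (the covering molecules are then partitioned by their
match-vector over the region, Hamming 2-medoid); (ii) an interior pile
of molecule ends — molecules stop at telomeres and fragile sites, so a
pile more than 2× the reporting resolution short of the terminus while
coverage continues marks a shorter co-assembled haplotype. When more
than one contig exists, a competitive round re-assigns every molecule
to the contig(s) within one match-reward of its best score and refines
each contig with its supporters only, which purifies both consensus
maps. Finally, overlapping consensus maps merge when their dovetail
agreement is high (≥75% of both maps' labels over the shared span) and
their telomeric termini are compatible — either agreeing within the
10-kb resolution or with the shorter map ending at a plain coverage
boundary rather than at an end pile. Distinct end-anchored termini are
exactly what distinguishes haplotypes, so such maps never merge.

Known limitation: a heterozygote whose two alleles differ *only* by a
terminal extension (no interior pattern change) separates through the
end-pile signal alone; if the shorter allele's end pile is weak (low
coverage), such an arm can assemble into a single, longer-allele contig.

## Calling

A contig anchors to the unique arm whose 1-copy interval contributes at
least 9 matched labels, with the best arm's score required to exceed
the runner-up by 20% — duplicated blocks are shared between arms and
must not drive assignment. The telomeric terminus is estimated as the
median of the distal pile of placed molecule ends (within 5 kb of the
maximum), projected into reference coordinates through a least-squares
affine fit of the matched pairs, and differenced against the annotated
arm end. Gap assessment follows the sign convention above: EXTEND
(positive), SUPPORTED (zero, or terminus inside the gap), DELETE
(at/before the gap start), INACCURATE (anchored but the distal
reference pattern is mostly unmatched). A telomere is confirmed when
≥3 telomere-labeled molecule ends sit within twice the optical
resolution of the terminus. INP (inverted nick pair) sites are adjacent
opposite-strand labels ≤1 kb apart (the distance is not constrained
further by any published value; 1 kb reflects that fragility requires
closely opposed nicks).

Haplotype clustering is single-linkage: contigs link when they
fit-align with ≥70% label agreement on both maps and their raw terminal
extensions differ by less than the 10-kb resolution; clusters are
numbered by size. An arm is HIGH variability when minor haplotypes
exceed 10% of represented maps — the boundary itself (exactly 10%)
is LOW, i.e. the minor share must strictly exceed the threshold.
Block detection fit-aligns each block's spacing pattern in both
orientations, requires ≥75% of the pattern's labels matched (≥3 labels
absolute — blocks with fewer nick sites are only analyzable through the
fixed combined groups), and selects non-overlapping hits greedily by
score. Block presence is one 0/1 per genome per arm (diploid double
carriers count once); frequencies divide carriers by genomes with an
anchored map for that arm in that super-population; per-block one-way
ANOVA across the five super-populations is Bonferroni-corrected across
the arms tested for that block, with `m` reported explicitly.

## Synthetic data

The generator emulates the study design rather than any real genome:
154 diploid genomes in five super-populations (42 AFR, 30 AMR, 30 EAS,
24 EUR, 28 SAS) by default; haplotypes composed of an arm-specific
1-copy anchor (random 8–16-kb spacings, shared by all haplotypes of an
arm) followed by named blocks from a shipped library of eight spacing
patterns (20–60 kb, 5–9 labels each, hand-designed with contrasting
rhythms and verified non-cross-aligning at detection thresholds);
molecule lengths shifted-exponential (min 150 kb, mean 300 kb, matching
the instrument's reported averages), truncated at the telomere and
clipped at the window's centromeric edge (molecules physically continue
proximally); false negatives by per-label Bernoulli(0.10); false
positives by a homogeneous Poisson process whose rate makes the
expected FP fraction 0.10 of true labels; per-interval multiplicative
Gaussian sizing noise (CV 0.02) plus 300-bp label jitter — magnitudes
chosen small enough that 10-kb calls are resolvable, as no published
values exist; labels closer than 1.5 kb merged to their mean; molecules
crossing an INP site split there with probability 0.9 (fragility is
described as near-complete but unquantified); fragments below 50 kb are
discarded as uninformative. Telomere labeling is a boolean end flag —
it is used only as an endpoint witness, so a separate label channel
would add nothing.

What the simulation does *not* model — chimeric molecules, non-uniform
label efficiency along the DNA, stretch-field distortions, image-level
noise, and the shared non-subtelomeric bulk of the genome — bounds what
green tests show about real data: they validate the algorithms against
the stated error model, not instrument physics.

## Benchmark scenarios and problem sizes

Four named scenarios pin the pipeline to known answers: a haplotype
extending 130 kb beyond its reference end (four extra blocks of
45+30+20+35 kb); a reference with an excess 110-kb terminal N-gap whose
true arm ends at the gap start (correction −110 kb, DELETE); a cohort
segregating a 45-kb terminal insertion (two clusters whose extensions
differ by 45 kb); and the variability boundary sweep (flip strictly
above 10%). The acceptance script runs each from scratch at the study
conditions (10% FP/FN, >150 kb molecules, 60× coverage). The insertion
cohort uses four homozygous genomes (three major, one minor): the
measured quantity is a per-contig length difference and does not depend
on cohort size, so a handful of genomes characterizes it; population-
scale behaviour (frequencies, ANOVA calibration and power at the real
super-population sizes) is exercised separately at the presence-matrix
level, where the full 154-genome design costs nothing.

## Numerical and reproducibility notes

All randomness flows from numpy Generators seeded through a documented
scheme (`child_seed(seed, label)` = a CRC32 mix of the stage label into
the global seed, kept below 2³¹), so stages re-run independently and
identically; the pipeline manifest records per-stage seeds and content
digests of every artifact. Degenerate inputs are defined throughout:
empty maps refuse to align; all-identical ANOVA groups return an
NA-flagged result rather than an F statistic; arms with no anchored
contigs are summarized with variability NA; a map shorter than the
minimum molecule length cannot reach coverage and raises. The in-silico
digest suppresses labels inside N runs by construction (the recognition
site is unambiguous) and keeps the '+' label when forward and reverse
occurrences coincide.
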