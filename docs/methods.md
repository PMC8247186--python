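# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## The data regime

The package targets single-cell whole-genome libraries built by
one-adaptor Tn5 tagmentation and sequenced as long circular-consensus
(HiFi) reads. The regime that shapes every algorithmic decision:

- fragments of ~6 kb (low-density transposition), all of them
  amplifiable — the one-adaptor design avoids the 50% fragment loss of
  two-adaptor chemistry;
- per-cell mean depth far below 1× (default 0.4×), so per-cell evidence
  for any locus is a Poisson draw with a small mean;
- consensus read accuracy near Q30, so base-level errors are rare but
  small indel artifacts are still common enough that indels under 100 bp
  are excluded from benchmarking.

Low per-cell depth is why every caller decision here leans on *recurrence
across cells*: amplification chimeras and other artifacts are private to
one cell, while clonal variants recur.

## ecDNA detection

A read that crosses the junction of a circular template aligns to the
linear reference as exactly two segments on the same chromosome and
strand in chiastic order; the inferred circle is `[start of read-later
segment, end of read-earlier segment)`. Operational definition
(`ecdna.detect_chiastic_reads`):

- exactly two aligned segments (reads with one or ≥3 segments are
  skipped);
- same chromosome and strand; minus-strand reads are first normalized to
  genome orientation, which swaps the segment order;
- query gap/overlap between the segments ≤ 50 bp (`max_query_gap`,
  tolerating junction soft-clips);
- genomic overlap between the segments ≤ 50 bp (`junction_tol`). This
  bound does double duty: it permits slightly overlapping junction
  alignments while rejecting reads that cover more than one circle
  length, whose alignments overlap heavily.

A read is flagged *full-length* when its two segments jointly cover ≥95%
of it. A circle that received exactly one transposition event produces
such a read with length equal to the circle length; independent copies
of the same circle therefore yield distinct reads of identical length
(`ecdna.same_length_evidence` groups full-length read lengths within
±20 bp and reports the modal group and its cell span). Tandem repeats
cannot produce this pattern.

Two confounders share the chiastic signature and are filtered in fixed
order (each stage only removes or merges, never invents candidates):

1. **Tandem repeats** — a junction breakpoint inside (or within 50 bp
   of) a tandem-repeat annotation longer than 1 kb is unmappable
   evidence; the candidate is removed. Only the junctions are tested:
   a circle may legitimately *contain* repeats.
2. **Head-to-tail duplications** — a genomic duplication junction
   produces exactly the same two-segment chiastic read. A candidate is
   removed when a consensus DUP call supported by ≥4 cells matches both
   junction coordinates within ±100 bp.

Surviving per-read candidates are merged across cells by single linkage
(both coordinates within ±50 bp; consensus at member-median
coordinates) and reported when supported by ≥1 read in each of ≥2
distinct cells. Mitochondrial candidates are reported separately — the
mitochondrial genome is a real circle and serves as a positive control,
not as a nuclear ecDNA call.

**DUP evidence vs circle evidence.** The minimal split-read extractor
(`svconsensus.extract_cell_svs`) must not call every chiastic read a
duplication, or circle junction reads would generate the very DUP
consensus that deletes them. The discriminator is read geometry: a
duplication junction read normally extends *beyond* the duplicated unit
on at least one side (the unit is shorter than the fragment), or wraps
the unit more than once; a circle read is confined to the unit. Chiastic
reads with >50 bp overhang or more than one wrap are emitted as DUP;
confined reads are left to the ecDNA stage. In the pipeline driver
(`ecdna.run_pipeline_with_dup_evidence`) any PASS DUP call counts as
duplication evidence regardless of per-cell read support — the ±100 bp /
≥4-cell requirement of the filter is its own specificity control, and
at 0.4× depth almost no single cell sees a junction twice.

## SV consensus and benchmarking

Per-cell filtration keeps PASS calls (IMPRECISE and SHADOWED flags are
dropped) with ≥2 supporting reads; bulk call sets require ≥4 reads and a
support ratio strictly greater than 15% of local depth. Indels under
100 bp are excluded from benchmarking.

Merging is single-linkage clustering per SV type: two calls link when
both breakpoints lie within 1 kb (translocations: both breakpoints
within ±50 kb, chromosome pair matching; a translocation is one logical
call with two breakpoints, serialized as a BND pair). Each cluster
becomes one consensus call at the member-median breakpoints with the
union of supporting cells; clusters below the cell threshold (default 2)
are dropped. The merge is invariant under permutation of input cells.
One caveat: median-consensus single linkage is idempotent only when
consensus calls stay farther apart than the linking distance —
adversarially interleaved clusters can produce consensus records that
link on a second pass. This cannot create false positives (all members
were real calls) and does not arise in the validation designs; it is
inherent to this merging strategy.

Benchmarking is distance/type matching with multimatch semantics: a test
call is a true positive when any truth call of the same type has both
breakpoints within 1 kb (±50 kb for translocations); several test calls
may match one truth record; unmatched truth records are false negatives.
Sequence-similarity matching is deliberately not implemented — matching
is purely positional. Metrics: Precision = TP/(TP+FP),
Recall = TP/(TP+FN), FPR = FP/(TP+FP) = 1−Precision, FNR = FN/(TP+FN),
HM = 2·FPR·FNR/(FPR+FNR), F1 = 2·P·R/(P+R). A 0/0 ratio is reported as
NaN rather than silently zeroed; HM and F1 use their well-defined limits
(0) when both inputs are 0. For cross-platform comparison with
short-read call sets, deletions match on reciprocal overlap strictly
greater than 10% of both intervals and insertions on breakpoints within
±1 kb.

**Duplication placement.** Each duplication midpoint is mapped to a
relative centromere→telomere position on its chromosome arm, pooled
across arms into 100 equal windows, and tested against the uniform
multinomial with a chi-square goodness-of-fit test (df = 99). Chi-square
was chosen as the standard goodness-of-fit test for binned counts; at
the design's 500 events the expected count per bin (5) is at the edge of
the usual adequacy rule, and the calibration test confirms the p-value
distribution is uniform under the null.

**SNVs.** Multi-cell support benchmarking keys SNVs by (chromosome,
position, alternative allele): a candidate supported by ≥k cells is a
true positive only when the bulk set carries the *same alternative
allele* — a bulk call at the same position with a different allele does
not count. Detection efficiency is TP/|bulk| and precision TP/(TP+FP).
The per-cell false-positive rate divides calls absent from bulk by the
cell's covered bases. The mutation spectrum collapses
strand-complementary substitutions into six classes (C→T ≡ G→A, etc.),
verifying each call's reference base when a reference is supplied.

## CNV profiling

Reads are counted once per read, in the 1 Mb window containing the
primary segment's leftmost position — at 1 Mb windows and ~6 kb reads,
assignment by overlap fraction would change almost nothing and
left-position assignment is deterministic. Window ratios (count/total)
are scaled by the unique constant making the mean over unmasked windows
equal the sample ploidy. Normalizing the genome-wide mean assumes
aberrant regions are a small fraction of the genome; the validation
design keeps its planted arm at 13% of windows for this reason.

The coefficient of variation is the sample standard deviation over the
mean (n−1 denominator; whether the population or sample form was used
historically is ambiguous, so the choice is recorded here and in output
metadata) of the per-window quotient cell/baseline, over windows
unmasked in both profiles. The baseline may be a bulk profile or the
mean of the single-cell profiles; the same formula applies. For a flat
profile of Poisson(λ) counts against a flat baseline the expected CV is
≈1/√λ, which the tests use as a calibration band.

Segmentation is circular binary segmentation in its basic form: for each
segment, the maximal absolute circularized two-sample t statistic over
all arcs, with significance from a permutation test (default 1000
permutations, α = 0.01) and recursion on accepted splits. The
within-segment standard deviation is used in place of the pooled
arc-specific estimate — the permutation reference absorbs the
approximation. No pruning or undo heuristics are applied: the target is
planted-breakpoint recovery, not equivalence with any particular
production implementation. Permutation streams are derived from
(seed, segment bounds), making results deterministic and ensuring that
tightening α can only reduce the number of segments. Chromosomes are
segmented independently; masked (gap) windows are excluded from the
statistic and carry no segment value. Profile correlation is the Pearson
r of per-window segment means with gap windows removed pairwise.

## The synthetic generator

`simulate.simulate_dataset` emulates the assay's generative process:

- **Reference**: i.i.d. uniform ACGT with explicitly written tandem
  repeat tracts (unit 10–100 bp tiled to 1.2–3 kb) — no attempt to mimic
  human base composition; chromosome arms put the centromere at 45%.
- **Fragmentation**: homogeneous Poisson cuts at rate 1/6000 bp⁻¹.
  Fragments tile the molecule exactly; all are retained (one-adaptor
  chemistry), and those under 1 kb are dropped only at read emission.
- **Cells**: diploid; planted variants sit on both haplotypes by default
  (a `homozygous=False` flag puts them on one), and `cell_fraction`
  implements subclonal structure. Each haplotype is fragmented
  independently; a fragment starting where the planted copy number is c
  is kept with probability coverage·c/(2·ploidy), so realized depth
  tracks the planted profile.
- **Alignments are derived analytically** from the donor-genome
  geometry: deletions/insertions shorter than the read appear as CIGAR
  D/I runs, duplication and circle junctions as chiastic split pairs,
  inversions as opposite-strand pairs, translocations as
  cross-chromosome pairs. Read mapping is upstream of this package, so
  simulating a mapper's behavior (soft-clip jitter, mapping error) is
  out of scope; junction coordinates in the emitted alignments are
  exact. Read base sequences are materialized only on request (SAM SEQ
  is `*` by default) since no downstream stage consumes bases.
- **Circles**: each copy in each carrying cell is cut independently;
  every arc ≥1 kb becomes a read and the arc crossing the origin maps
  chiastically. A copy with no cut is never linearized and yields
  nothing. The truth table records which cells produced chiastic reads
  per circle — the denominator for recovery scoring.
- **Call-set noise**: emitted per-cell SV calls are the planted variants
  covered by ≥1 junction-spanning read (support = that count) plus
  Poisson-distributed spurious calls at uniform loci, private to one
  cell with support 1–2 — the mechanism that makes multi-cell support
  informative. SNV call sets likewise combine coverage-thinned truth
  with private per-base false positives; consensus errors are modeled as
  uniform substitutions only, since sub-100 bp indels are filtered
  downstream anyway.

Determinism: all randomness flows from the config seed through spawned
generators; identical configs give byte-identical output files.

**What the simulator does not model**, and hence what passing tests do
not show about real data: PCR bias and chimera formation (only their
*effect* — private spurious calls — is modeled), mapper behavior on
repetitive sequence, GC/mappability waves in coverage, indel sequencing
errors, aneuploid karyotypes beyond planted steps, and circles with
multi-segment internal structure. The relation between depth and genome
breadth additionally depends on amplification duplicates that are not
modeled; coverage (depth) is the controlled parameter and breadth is
reported, with no claim to match any particular breadth/depth ratio.

## Validation designs and problem sizes

The reference designs (`sclongread.designs`) use 30 cells at 0.4× on a
60 Mb single-chromosome genome for circle recovery (20 circles of
5–200 kb, upper size capped so multiple circles fit the chromosome),
plus 10 clonal 2–5 kb head-to-tail duplications and 20 repeat-tract
junction circles for the confounder design; 40 clonal SVs with 50
private false calls per cell for the consensus sweep; 4×30 Mb
chromosomes for CNV (one arm at copy 2 of ploidy 3, λ ≈ 57 reads per
window); and 20 Mb / 12 cells / 3000 bulk SNVs at a planted 2×10⁻⁵
per-base false-positive rate. These sizes keep each design's simulation
in seconds while preserving the full-genome values of every per-locus
rate the methods depend on.

## Known limitations

- The chiastic detector requires *exactly two* segments, so circles
  longer than a read that need multi-junction assembly, and circles with
  internal rearrangement, are out of scope by design.
- Beyond the ±100 bp duplication filter there is no way to distinguish a
  circle from a co-located duplication; candidates removed there may
  include real circles that overlap duplications.
- The bulk SV path expects calls with support and depth annotations; the
  package does not itself call SVs from bulk alignments beyond the same
  minimal extractor.
- `merge_across_cells` idempotence caveat above.
- VCF support is a subset: symbolic ALTs for DEL/INS/DUP/INV, BND pairs
  for translocations; no nested or multi-allelic records.
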