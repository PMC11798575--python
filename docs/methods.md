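# Methods

## Barcode model and assignment

A barcode reference is an ordered set of 14-bp ACGT sequences with unique
IDs (length configurable; 14 throughout this note). "Mismatch" means
substitution only: every comparison is between fixed-length windows, which
excludes indels by construction, so the distance is Hamming distance. The
reference loader rejects N and other ambiguity codes — references are
curated sequences, and silently wildcarding them would weaken the
uniqueness guarantees of assignment. `validate_reference` reports every
reference pair at distance ≤ 2·m for the working mismatch budget m: by the
triangle inequality these are exactly the pairs for which some query window
could sit within m of both, i.e. the pairs that can produce ambiguous
reads. It reports rather than enforces, since a deployed barcode set may
tolerate known near-pairs.

Read assignment is a two-stage scan:

1. **Handle location.** The fixed 20-bp PCR handle is searched at start
   offsets 0..`max_search_offset` (default 10), accepting the smallest
   offset whose window matches the handle with ≤ `max_handle_mismatch`
   substitutions (default 1). The offset scan covers the 0/2/4/6-base
   frameshift spacers of the amplification primer pool plus margin.
   Fixed-offset substitution-only scanning is deterministic and
   bit-reproducible; adapter-trimming heuristics with unstated tolerances
   are deliberately avoided.
2. **Barcode assignment.** The 14 bases following the handle are compared
   to every reference barcode. If the minimum distance is ≤ 2 and achieved
   by exactly one barcode, the read is assigned at that distance; a
   within-tolerance tie is `ambiguous` (excluded from counts, tallied in
   QC — fractional splitting would be nondeterministic in effect and
   inflate close pairs); a minimum above tolerance is `no_match`. Reads
   whose post-handle suffix is shorter than one barcode are `too_short`;
   reads without a handle hit are `no_handle`. Quality scores are never
   used.

The per-sample QC tallies satisfy, and the code enforces,
`n_total = n_assigned + n_no_handle + n_too_short + n_no_match +
n_ambiguous`. The production path is a vectorized numpy batch
implementation (reads packed into a padded byte matrix; one broadcasted
mismatch count per offset and per reference); a scalar reference path
(`assign_read`) implements the same contract, and the test suite checks
both against an independent brute-force oracle.

Abundance fractions divide counts by **assigned** reads, not total reads:
unassigned reads carry no barcode information, and fraction-of-assigned is
the only normalization under which an even input pool is expected at
1/n_barcodes. Samples with zero assigned reads yield an all-zero row and
are flagged rather than divided.

## Behavioral statistics

* `scale_to_flies`: abundance × per-tube fly count, giving fly-equivalents;
  each tube row sums to its counted fly number.
* `preference_index`: (L − D)/(L + D) on fly-scaled counts, flagged
  undefined when a barcode contributes nothing to either tube. Fly-scaled
  counts are always used; when the two tubes hold equal fly numbers this
  coincides with the abundance-fraction form.
* `replicate_summary`: mean, SEM and CV across replicates. SEM uses the
  n−1 sample standard deviation (the usual error-bar convention); with one
  replicate SEM is reported as 0 and flagged uninformative; CV is flagged
  undefined at mean 0.
* `expected_observed_fit`: R² is the squared Pearson correlation of the
  (expected, observed) pairs — equivalently the OLS R² with intercept, and
  invariant to which variable is on x — with OLS slope/intercept reported
  alongside. With a grouping, observed values are averaged within each
  input level first (abundances are averaged, not ranks), giving one point
  per level. `paired_measure_correlation` is the same contract with a
  manual measurement on the x-axis.
* `timecourse_summary`: per barcode, the cumulative fraction passed by
  time t over ordered timepoint bins. Animals in the "never passed" bin
  remain in the denominator (they genuinely did not pass within the
  assay); animals in the "died" bin are excluded from it, so mortality is
  not conflated with motility. The median transit time is the first bin
  whose cumulative fraction reaches 0.5, flagged censored if never
  reached. Curves are non-decreasing and bounded by 1.

## Single-cell assignment

Enriched records (cell barcode, UMI, tag read) are filtered — N in cell
barcode or UMI, off-whitelist cells, unassignable tag reads (same
trim-and-assign procedure as amplicon reads) — then deduplicated so each
(cell, UMI) contributes at most one count. When one UMI's records disagree
on the tag (a PCR chimera signature), the majority tag wins and exact ties
are dropped; majority voting is the standard deterministic
chimera-suppression choice. No UMI-sequence error correction (1-mismatch
UMI collapsing) is performed; with 12-base UMIs at the depths involved,
UMI collisions are negligible next to chimerism, and skipping correction
keeps dedup exactly reproducible.

Per cell, **purity** = top-tag UMIs / total tag UMIs (undefined with no
tag UMIs; on a top-count tie the purity value stands but the top tag is
undefined, so no enriched call can be made). Calls merge two sources:

* **GE call**: the unique tag with count ≥ `ge_min_count` (default 1 — no
  expression threshold is imposed beyond detection) in the GE matrix; two
  or more such tags mark the cell a barcode doublet.
* **Enriched call**: the top tag iff purity > 0.75 (strict) and the top is
  unambiguous.
* **Final call**: the GE call when it is a single tag — direct detection
  in the expression library takes priority on conflicts — otherwise the
  enriched call, otherwise none.

Detection fractions are computed over cells present in the GE matrix only:
cells appearing solely in the enriched library never passed expression QC
and are excluded from denominators. `detect_tag_doublets` returns cells
with ≥ 2 tags at ≥ `min_count` in GE; `overlap_stats` compares that set
with an external doublet caller's output by plain set arithmetic. The
purity–concordance curve buckets cells having both a single GE tag and an
enriched top tag by purity and reports per-bin agreement, exposing
empirically where enriched evidence stops being reliable instead of
hard-coding an upper purity cutoff.

## Synthetic data

`sim_amplicon` emits reads of the form spacer + handle + barcode + 30 bases
of fixed downstream (SV40-side) context, with i.i.d. per-base substitution
errors. Spacers are the actual 0/2/4/6 frameshift bases of the
amplification primer pool, mixed uniformly by default (the primers are
pooled evenly). Chimeras resample the barcode window from the pool
distribution independent of the template — the template-switching
mechanism — and the truth table records both template and emitted barcode
per read. Allocation is multinomial, or largest-remainder rounding under
`exact_allocation` for exact-recovery tests. Quality strings are constant:
qualities are ignored downstream, and a quality model would add
unconsumed complexity.

`sim_phototaxis` sends each fly to the light tube with probability
(1 + P.I.)/2, records realized tube compositions, and simulates reads per
tube from them, so estimator error can be decomposed into sampling
(binomial) and sequencing components. `sim_sc` draws each cell's genotype
from configured proportions, adds a second independent draw for doublets
(a repeated draw gives an undetectable homotypic doublet, as in real
droplets), generates GE tag counts as Poisson(`ge_capture`) per carried
tag — so the GE detection fraction of singlets has the closed form
1 − e^(−μ) used in tests — and enriched UMIs as
Poisson(`enriched_umis_per_cell`) split uniformly across carried tags,
with per-UMI ambient swaps and per-record chimeric swaps at configured
rates. `sim_transit` allocates larvae multinomially across timepoint bins
including terminal never-passed/died bins.

Default noise levels used in the benchmark configurations — 0.5% per-base
substitution error, 1% amplicon chimera rate, 100,000 reads per pool, and
for single cells ~20 enriched UMIs per cell with 2% ambient and 5%
chimeric noise — are ordinary magnitudes for short-read amplicon data and
nested-PCR droplet libraries.

What the simulations do **not** model: indels and quality-correlated
errors (the assignment procedure is substitution-based, so indel-rich
platforms would need upstream handling), transcriptome-wide expression
(only tag features are simulated on the GE side), cell-calling artifacts,
ambient RNA beyond the tag channel, and library-size variation across
cells. Passing recovery tests therefore demonstrates correctness of the
counting and calling logic under the stated noise model, not robustness to
every failure mode of real libraries.

## Numerical and interface choices

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs. Tabular interchange is TSV; CLI outputs
round floats to 6 significant digits for stable diffs. Every CLI run
writing an output directory records a manifest (parameters, input SHA-256
checksums, version). Abundance row sums are validated to 1e-9; fly-scaled
tube rows to 1e-6. FASTA/FASTQ parsing uses Biopython (gzip accepted
transparently); sparse GE matrices use the standard matrix-market trio in
the features × cells orientation.

## Problem sizes

The test suite and acceptance script run pools of 20 barcodes at
100,000 reads (triplicate for the even-pool benchmark), phototaxis
recovery at 10,000 flies per genotype and 50,000 reads per tube, and
single-cell simulations of 3,000–5,000 cells, chosen so every benchmark's
sampling error is well inside its acceptance band.

## Known limitations

* The handle locator is substitution-only; an indel inside the handle or
  barcode shifts the window and typically demotes the read to `no_match`
  or `no_handle` rather than recovering it.
* Ambiguous reads are dropped, which slightly under-counts barcode pairs
  closer than 2·max_mismatch; `validate_reference` surfaces such pairs up
  front.
* Purity gating cannot rescue cells whose enriched evidence is a
  high-purity chimera (few UMIs, all wrong); the purity–concordance curve
  is the diagnostic for choosing a stricter gate when needed.
* The GE-priority merge trusts any single-tag GE detection at
  `ge_min_count`; raising the threshold trades detection fraction for
  robustness to ambient tag transcripts.
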