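# Methods

## Model and assumptions

splicemark treats alternative splicing detection as a *presence* problem:
a splicing event (a junction between two transcript regions, or coverage
of a single exon/intron) is either observed in a sample or not, and a
biomarker is an event whose presence pattern differs between two groups.
This deliberately avoids isoform-abundance modelling (no PSI, no
transcript quantification): the downstream proteome stage can only see
presence ("hits"), so the RNA stage uses the same semantics end to end.
A read-count mode (`--test-mode counts`), which tests an event's group
read totals against the complement of all other events, is provided for
sensitivity analysis but is not the default.

Assumptions worth stating explicitly:

- The transcript model is trusted: junctions are only interpreted
  relative to annotated exon/intron structures, and a junction matching
  several transcripts yields one event per transcript (biomarkers are
  reported at transcript level).
- Junction blocks behave like maximal read overhangs: a genuine
  junction block lies (almost) entirely inside one region, which is why
  the overlap rate is asymmetric (denominator = block width) and the
  90% acceptance threshold is meaningful.
- Samples are exchangeable within a group; the chi-square on the 2×2
  presence table assumes independent samples and moderate group sizes.

## Coordinates and indexing

All internal coordinates are 0-based half-open on the forward strand;
GTF (1-based inclusive) and BED (0-based half-open) are converted at the
I/O boundary so that interval arithmetic has a single convention. Exons
and introns are indexed in transcription order (EXON1 = 5'-most), which
makes category labels biologically meaningful on both strands; for a
two-block junction on a minus-strand transcript the genomically-left
block is therefore the 3' side and the pair is flipped before labelling.
Two blocks that both map to introns fit none of the six categories and
are treated as unannotated.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_overlap` | 0.90 | per-block overlap-rate threshold (fraction) |
| `min_reads` | 6 | pooled read support required per event |
| `support_scope` | pooled | pool counts across samples vs. require one sample |
| `presence_min` | 1 read | sample counts as "present" at this depth |
| `q_max` | 0.05 | q-value cutoff, both stages |
| `flank` | 120 nt | flank taken on each side of the junction |
| `min_peptide_len` | 6 aa | tryptic-detectability floor for DB entries |
| `fdr_max` | 0.01 | target-decoy prefix-FDR bound |
| `evalue_max` | 0.1 | hard E-value cap on accepted PSMs |
| `min_hits` | 2 | minimum sample hits in one group per peptide biomarker |

The 120-nt flank reflects tryptic fragment lengths observable in MS/MS;
with a typical search engine enforcing fully tryptic peptides, a longer
flank adds almost no observable peptides while inflating the database.
The 6-aa floor drops translation fragments a search engine could never
confidently match. The ≥ 6-read support filter is applied to the count
pooled over samples; a per-sample variant is available because the
choice is a genuine judgment call (pooling favours recall in small
cohorts, per-sample favours precision).

## Numerical choices

- **Chi-square**: Pearson, df = 1, no continuity correction by default
  (`--yates` enables it). Tables with a zero marginal are degenerate and
  return (statistic 0, p 1) instead of erroring, so all-absent or
  all-present events simply rank last.
- **Storey q-values**: π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid
  λ = 0, 0.05, …, 0.90, smoothed with a natural cubic spline and read
  off at λ = 0.90, clipped to (0, 1]. For m < 100 tests the spline
  estimate is noise-dominated, so π₀ falls back to 1 and the q-values
  coincide exactly with Benjamini–Hochberg (asserted against an
  independent BH implementation in the tests).
- **Argmax tie-breaks** in region assignment: equal overlap rates prefer
  the exon over the intron, then the lower region index — deterministic
  and biologically conservative (exonic evidence is the less surprising
  explanation).
- **FDR cutoff ties**: all PSMs sharing the cutoff E-value are evaluated
  as one prefix and accepted together (inclusive threshold). The
  estimator is #decoys/#targets on the sorted prefix; the cutoff is the
  largest E-value whose prefix passes, so the bound is tight: the next
  larger observed E-value always violates it.
- **Frame inference**: Ensembl phase gives the codon position of an
  exon's first base; a flank starting at offset *o* in the exon begins
  at codon position (phase + o) mod 3 and translation skips
  (3 − position) mod 3 bases. Unknown phase (−1) falls back to
  three-frame translation keeping the longest stop-free peptide (ties:
  lowest frame, earliest start).
- **Decoys** are full-sequence reversals, one per target entry, giving
  decoy and target databases identical size and length distribution.
  Palindromic peptides (decoy = target) are logged.

## What the generator emulates — and what it does not

`splicemark.simulate` produces a toy genome (default 12 genes, 3–5 exons
of 150–300 nt, introns 90–200 nt, alternating strands), per-sample
BED12 junction tracks and region-coverage TSVs, and OMSSA-style PSM
CSVs. Background evidence (a normal junction per neighboring exon pair
and first-exon coverage, present in every sample) surrounds planted
events — one per category by default — included with probability 0.8 in
the cancer-like group vs 0.1 in the normal group across 20 + 20 samples.
Read counts follow a shifted negative binomial (n = 4, p = 0.3). At the
PSM stage each database peptide emits per-sample with probability 0.7
vs 0.05 (planted direction), decoy entries emit at 5% per sample, and
decoy E-values are log-normal around 10^0.7 against 10^−4 for true hits.

These sizes are the package's default desk-scale study: large enough
that the closed loop (simulate → annotate → test → builddb → simulate
PSMs → msfilter) exercises every category and both multiple-testing
regimes, small enough that a 20-seed recovery experiment runs in
seconds.

The generator does **not** emulate: read-level sequences or alignment
artifacts (soft-clipping, multimapping, Tophat's re-mapping of initially
unmapped reads), overlapping genes or multi-isoform loci, library-size
variation between samples, spectra or search-engine score correlations,
or shared peptides between proteins. Passing closed-loop tests therefore
demonstrates the correctness of the annotation/statistics/database/FDR
machinery under clean evidence, not robustness to alignment noise or to
ambiguous gene models.

## Design decisions on genuinely open points

- **Flank source is region-limited**: the 120-nt flank is taken within
  the event's own left/right region, not from spliced transcript
  context spanning further exons. This matches synthetic-AS-database
  construction practice and keeps every database entry attributable to
  exactly two regions.
- **Single-region events use the region's first 120 nt** (not the 120 nt
  preceding it) — the alternative would describe sequence outside the
  labelled region.
- **Both blocks must pass the 90% threshold individually** on the same
  transcript before a junction annotates to it.
- **"Longest peptide" is not required to span the junction**; records
  report whether it does (`spans_junction`), and the report notation
  marks the splice site with `^` (between codons) or `(X)` (codon
  spanning it).
- **Storage**: transcript models are held in in-memory indices
  (intervaltree over transcript spans); no relational backend.
- **FDR estimator** is #decoys/#targets rather than 2D/(T+D);
  configurable at the API level, and the pooled-vs-per-sample scope of
  the cutoff is a flag (`--per-sample-fdr`), pooled by default.

## Known limitations

- Presence/absence testing discards read-depth information; weakly but
  consistently included events need the counts mode.
- Chi-square p-values are asymptotic; with very small groups the
  discreteness of 2×2 tables makes the null rejection rate fall below
  nominal (the test suite checks calibration at 20 + 20).
- Events are keyed by (category, transcript, regions); identical
  junctions shared by two transcripts are counted per transcript, which
  inflates event totals relative to a junction-level count.
- The PSM stage trusts the search engine's E-values; no rescoring,
  charge-state or retention-time modelling is attempted.
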