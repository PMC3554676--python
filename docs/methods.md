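# Methods

## Read accounting

Reads failing the quality screen (any `N`, or mean Phred < 20 — the
conventional reading of an otherwise unspecified "low quality" filter) are
excluded before categorization; the surviving count is the *high-quality*
denominator for all report percentages.  Each high-quality read then lands
in exactly one terminal category, tested in this order: 5'-adapter
carry-through (the adapter-5 3'-terminal 8-mer found within the first
`len(adapter5)` bases), missing 3' adapter (the adapter-3 5'-terminal 8-mer
absent), empty insert (adapter at position 0), insert < 18 nt, polyA insert
(≥ 90 % adenine), clean.  Adapter matching is exact on a configurable-length
prefix (default 8 nt); substitution-tolerant matching is deliberately off —
the simulator's substitution-only error model and the exact-prefix trimmer
are designed as a matched pair, so a base error in the adapter prefix sends
the read to `adaptor3_null` exactly as unresolvable reads are discarded in
practice.  Percentages are rounded half-up at two decimals; half-up (not
banker's) matches how such tables are conventionally printed.

Collapsing keeps one tag per distinct insert sequence with per-library
counts, sorted by descending total count then sequence, so all downstream
output is deterministic.

## Classification

Tags are matched to the genome by perfect full-length string search on both
strands; only perfect hits count, and a tag with no hit is classified
`other` (it can still be counted, but is excluded from locus-based classes
and from library sizes).  Classification precedence is
rRNA > tRNA > snRNA > snoRNA > known_miRNA > siRNA > exon_antisense >
exon_sense > intron_antisense > intron_sense > other; a multi-mapping tag
takes the highest-precedence class over all its hits and is counted once.
"Known miRNA" means exact, full-length equality with a mature reference
entry.  siRNA requires explicitly annotated intervals — no de-novo siRNA
inference is attempted.  GFF3 input (1-based, closed) is converted to
0-based half-open coordinates at the parsing boundary and nowhere else.

Family aggregation parses the miRBase numerical identifier from mature
names (`zma-miR156a-5p → MIR156`); unparsable names fall into family
`UNKNOWN` with a warning rather than an error.

## Differential abundance

Library sizes default to genome-matched clean totals (the same denominator
the per-class composition table uses); clean-read totals are selectable.
Fold changes are raw-count ratios rounded half-up to one decimal.  The
default test is Fisher's exact two-sided test on the 2×2 table
`[[count, libsize − count]]` per library — exact at any count and
conservative when counts are small; Audic–Claverie (negative-binomial
posterior predictive, two-sided by doubling the smaller tail) and a pooled
two-proportion normal test are available alternatives.  No multiple-testing
correction is applied by default (single-table reporting at P ≤ 0.01);
Bonferroni and Benjamini–Hochberg are available by flag.  With one library
per condition the test measures sampling variability only, not biological
variance — a stated limitation of the design, not of the implementation.
Note also that composition matters: when abundant families truly fall,
flat families' *proportions* rise, and the exact test will flag them; only
fold-change magnitude distinguishes compositional from planted signal.

## RNA folding model

The built-in folder minimizes a reduced nearest-neighbor free-energy model
over pseudoknot-free structures:

* stacking energies for adjacent pairs from a symmetric 6-entry table over
  pair types (G:C, A:U, G:U) with coarse Turner-like magnitudes
  (−3.3 … −0.5 kcal mol⁻¹);
* hairpin loops of size s ≥ 3: 4.5 + 1.2·ln(s/3);
* bulge/interior loops of n unpaired bases: 2.0 + 1.0·ln(n);
* multiloops: 4.6 + 0.4 per branch + 0.1 per unpaired base;
* no dangling ends, coaxial stacking, or tetraloop bonuses.

The destabilizing loop terms are essential, not cosmetic: with stacking
alone, random 400-mers fold to absurdly low energies (observed
≈ −215 kcal mol⁻¹) because nothing penalizes chaining isolated complementary
patches, and hairpin discovery then loses precision to spurious duplexes in
random windows.  With the loop terms, random sequence stays largely
unpaired while true near-perfect stems still reach −30 … −60 kcal mol⁻¹.

The dynamic program is O(n³) (interior loops capped at 30 unpaired bases,
the standard trade-off) with numba-compiled fill and Python traceback.
`structure_energy` scores an arbitrary dot-bracket string under the same
model **without** the interior cap and is the model's definition; the test
suite verifies the DP against exhaustive enumeration of all nested
structures for short sequences.  Any engine returning `(dotbracket, mfe)`
can substitute via the backend hook; an `RNAfold` adapter is included, and
because its full Turner model assigns different absolute energies, the
−20 kcal mol⁻¹ threshold should be revisited when switching backends.

## Hairpin criteria

For each unannotated mapped tag, two windows are cut per hit — tag 20 nt
from the window's 5' end extending `flank` (default 250 nt) 3', and the
mirror — so a precursor is captured whichever arm the mature sits on; 250 nt
covers the 64–371 nt precursor lengths and ≤ 240 nt loop distances seen in
plant miRNA annotation.  After folding:

* **star inference.** The miRNA\* is the *dominant duplex block*: the
  longest run of mature positions whose partners decrease strictly with
  gaps bounded by the unpaired budget.  Short helix extensions of the
  mature into the loop or flanking sequence form separate blocks and their
  mature positions count as mismatches; without this, a perfect stem whose
  terminal base pairs one step into the loop would be mis-measured.
* **criteria**, tested in order with the first failure reported: mature
  20–22 nt; a partner block exists, lies entirely on one side, and the
  mature does not pair with itself (hairpin/one-arm); mature positions
  outside the block ≤ 6 (mismatch budget); unpaired bases inside the star
  span ≤ 6 (unpaired budget — two independent budgets, both configurable,
  since "unpaired" and "mismatch" limits are quoted interchangeably in the
  field); the star span pairs back exclusively into the mature (no
  loop/break); mature–star distance within 5–240 nt; precursor MFE
  ≤ −20 kcal mol⁻¹ (recomputed on the trimmed mature…star span with
  boundary-crossing pairs dropped); |MFEI| ≥ 0.85, the common plant
  convention (the criterion is only qualitative — "high MFEI" — in the
  literature, so the floor is configurable).

Acceptance is monotone in every threshold (loosening any one never shrinks
the accepted set), which the suite checks directly.  Candidates are
deduplicated by (locus, mature) keeping the lowest MFE; finally,
candidates with overlapping precursor loci on *either* strand collapse to
the most abundant tag — the dominant arm is the mature, the opposite arm
is the star (the reverse complement of a hairpin is itself a hairpin, so
strandedness cannot separate them).  Sequenced star support is then counted
for tags matching the star span within ±2 nt (the 2-nt overhang of Dicer
processing blurs exact ends).

## Target rules

Duplexes are ungapped (the positional rules speak of mismatches, never
bulges).  Positions are numbered 1..L from the miRNA 5' end; both G:U
orientations count 0.5 mismatch points.  G:U wobbles contribute to the
point totals (rules 1 and 5) but are not "mismatches" for the adjacency
rules 2–4 — half a mismatch for counting, not for adjacency.  Scanning is
exhaustive over every transcript window of miRNA length on the sense strand
only (mature mRNA).  The canonical cleavage coordinate is the transcript
base opposite miRNA position 10; an observed 5' fragment end is canonical
iff it equals that coordinate, and ends outside the site ± 5 nt are flagged
out-of-range.

## Enrichment

Upper-tail hypergeometric per term (P[X ≥ k] for k of n target genes
carrying a term present in K of N background genes) with BH adjustment
across terms; the background defaults to all transcripts supplied.  The
miRNA abundance filter keeps those sequenced strictly more than 50 reads
per million (normalized scale).

## Synthetic study generator

The generator emulates the structure of a two-library plant small-RNA
experiment; every output is a deterministic function of the master seed,
with one RNG stream per output file.

* **Genome** (default 100 kb): random sequence hosting, at non-overlapping
  loci: 25 hairpin precursors, 30 known-miRNA loci (10 families with
  miRBase-style names), 20 structural-ncRNA loci (rRNA/tRNA/snRNA/snoRNA/
  siRNA), and 8 two-exon genes.  Precursors are built stem-first — random
  20–22 nt mature (60 % 5'-U, the known bias), 0–2 non-pairing star
  substitutions, 24–60 nt loop — giving 64–110 nt precursors inside the
  observed 64–371 nt range, then validated by *running the discovery path
  itself* (window extraction, folding, all criteria) with rejection
  sampling, so planted truth provably satisfies the evaluator.
* **Tag pool**: known matures carry heavy lognormal read mass; novel
  matures are rare and their stars 50-fold rarer; ncRNA/genic fragments and
  unannotated genomic tags make up the bulk, with insert lengths drawn from
  a 20–24-dominated 16–30 nt profile (both ends of the gel-purification
  range are exercised against the ≥ 18 nt filter).  Tags that would not
  survive trimming deterministically (adapter motifs, polyA, N) are
  excluded at construction.
* **Fold changes**: DS:GS rate ratios are planted per family (defaults
  include 6.0, 5.0, 4.0 down and 0.25, 0.2 up, remainder flat) or per tag.
  Within each library, rates w·2r/(1+r) and w·2/(1+r) are normalized to
  probabilities, so the *rate* ratio is exactly r while realized *count*
  ratios additionally carry the global composition factor — exactly as in
  real libraries; the truth set records the exact per-library
  probabilities so tests have a sharp binomial oracle.
* **Libraries** (default 2 × 10⁵ reads): multinomial sampling over tags
  plus spiked junk — no-adapter (0.6 %), empty-insert (0.05 %), 5'-adapter
  carry-through (0.3 %), short-insert (1 %), polyA (0.08 %), and
  low-quality N reads (3 %) — then insert+adapter reads truncated to 40 nt
  with substitution errors at 10⁻³ per base (no indels, matching the
  exact-prefix trimmer).
* **Transcriptome**: 40 random transcripts of 600–1200 nt carrying planted
  target sites — perfect (score 0), single-wobble (0.5), double-mismatch
  (2.0), and deliberate rule-4 violations flagged `should_pass: false` —
  each validated through the duplex scorer at build time; target-carrying
  transcripts share a planted enriched term and every transcript gets ≥ 1
  background term.

What the generator does **not** emulate — ligation bias, PCR duplicates,
indels, quality-score structure, paralogous/repetitive genomic context,
isomiR end-heterogeneity, biological replicate variance — bounds what
passing tests demonstrate: the pipeline recovers planted truth under clean
multinomial sampling; robustness to those real-data pathologies is untested
by design.

## Problem sizes and numerics

The end-to-end validation uses two 10⁵-read libraries over a 100 kb genome
(≈ 2 500 distinct tags, ≈ 500 folded windows of ≤ 521 nt) — a scale chosen
so the complete study (simulate + pipeline) runs in about two minutes on a
single CPU while every stage still sees all read categories, all annotation
classes, multi-member families, and tens of hairpins.  Energy comparisons
use absolute tolerance 10⁻⁴ in traceback (well below the 0.1 kcal mol⁻¹
parameter granularity); report rounding is decimal half-up at the printed
precision; ratio of 0/0 is reported undefined and n/0 as infinite,
excluded from tables.  Degenerate inputs (empty libraries, zero depth,
zero GC, all-unpaired folds, empty transcriptomes) return empty results or
explicit errors as documented per function.

## Known limitations

* The reduced energy model ranks structures like a full Turner model at toy
  scale but its absolute energies are coarse; thresholds tuned for mFold or
  RNAfold energies transfer only approximately.
* Exact-match mapping and trimming make the pipeline blind to indel errors
  and isomiR variation.
* With single libraries per condition, "significance" quantifies sampling
  error only, and compositional shifts can flag truly flat families.
* The discovery dominant-arm rule assumes the mature outnumbers the star;
  loci where the annotated star dominates (a known biological reality)
  would be reported with arms swapped.
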