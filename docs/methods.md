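# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, the numerical conventions, and what the synthetic
test system does and does not establish about real data.

## Sequence model and coordinates

All coordinates are 0-based half-open on the forward strand; GFF3 emission
converts to 1-based inclusive. Chromosomes carry a circularity flag.
Ambiguity codes are tolerated everywhere but never match a seed k-mer, are
excluded from GC denominators, and exclude an alignment column from π and
Ka/Ks comparisons.

## Seeded homology engine

Read recruitment, dispersed-repeat detection, inter-genome fragment search
and synteny blocks share one seed–chain–verify engine
(`mitocharter.homology`):

1. exact k-mer seeds between query and target, both strands;
2. clustering on exact diagonals (query gap ≤ `max_gap`), then band-merging
   of nearby diagonals (|Δdiag| ≤ `band`) to admit small indels. Both the
   merged clusters and their exact-diagonal components are verified — a
   stray random seed merged into a genuine cluster would otherwise widen
   the verification window and dilute the measured identity of short hits;
3. verification by infix (HW) edit-distance alignment of the seeded core
   within a padded target window (so padding never contributes alignment
   columns), followed by ungapped X-drop extension of the flanks under
   +2/−3 scoring with X-drop 12. Identity = matches / alignment columns,
   gap columns included;
4. screening on alignment length, identity and a Karlin–Altschul E-value
   with the blastn-default reward/penalty (+2/−3; λ = 0.625, K = 0.41, gap
   columns scored as mismatches), E = K·m·n·e^(−λS).

Defaults: word size 7 for dispersed repeats (sensitivity down to ~27 bp
copies), 9 for transfer fragments (minimum 30 bp), 11 for synteny blocks
(minimum 300 bp), 15 for read-vs-read matching (long reads, chaining gap
500 bp, band 50). The E-value search space is the product of the two
genome lengths for transfer fragments, and the product of the two
*compared chromosomes* for the within-genome dispersed scan — with a
genome-wide space even a perfect 27 bp copy would exceed E = 1e-5 and the
shortest reported dispersed repeats could never appear.

Because flank extension is ungapped and X-drop–limited, a reported hit is
the maximal-scoring local alignment around the seeds; hits whose true
identity sits exactly at a screening threshold are classified either way
by the few flank columns the extension legitimately includes, which is why
the synthetic truth plans place planted features strictly inside the
screens (see below).

## Read recruitment

`select_candidates` marks a read as candidate when some chained match to a
core-gene sequence exceeds 50 bp. `choose_seed` ranks candidates by
(number of distinct core genes matched, identity-weighted matched bp),
with the read id as a deterministic tie-break; `per_gene=True` keeps the
best candidate per gene so the seed set touches every chromosome carrying
a core gene — on a multichromosomal genome a single global best seed would
strand the other chromosomes, since recruitment spreads only through read
overlaps. `recruit_iteratively` is a breadth-first sweep: an iteration
adds every unrecruited read whose matched alignment span against a
previously recruited read is ≥ 1 kb at ≥ 70% identity (containment counts;
dovetail is not required), so the result is independent of read order.
Reads shorter than the overlap threshold are provably unrecruitable and
skipped. Termination is a fixpoint (no additions) or an iteration cap
(default 50). Identity is computed over the full matched span including
gap columns — the conservative convention.

## Codon statistics

The standard genetic code is used throughout; plant mitochondria translate
with it. RSCU uses one family per amino acid (Ser, Leu, Arg as single
6-fold families); single-codon families (Met, Trp) are identically 1, so
an RSCU of 3 for ATG, as sometimes reported, is not reproducible under any
standard definition and is not attempted. Stop codons are tallied
separately and never enter RSCU or Nc. For Nc, 6-fold families feed the
F̄₆ term; a degeneracy class with no estimable family (all families with
n < 2 or F̂ = 0) borrows the mean of the estimable classes, and the result
is clamped to [20, 61]. Note that for finite n a perfectly uniform table
estimates F̂ slightly below 1/k, so uniform usage clamps at exactly 61.
Start/stop tallies weight genes by copy number and count edited stops
(e.g. `CGA(TGA)`) as the post-editing codon, which is what the ribosome
sees. Duplicate gene copies are counted once per distinct sequence by
default ("unique CDS" mode); pass every copy explicitly to weight by copy
number.

## RNA editing

The hydrophobicity partition is the unique two-class map consistent with
the full published transition taxonomy: hydrophobic = {A, I, L, F, M, P,
V, W}, hydrophilic = the remaining twelve; glycine and other residues
unreachable by C→U edits default to hydrophilic. A codon edited at both of
positions 1–2 is one event whose position is the 5'-most edited base, with
an `n_edited_bases` field. Stop-gain edits are possible only from Arg/Gln
codons (both hydrophilic), so the stop class is `hydrophilic-stop`.

The predictor aligns the translated CDS globally to each reference protein
(match 1, mismatch −1, gap open −2, extend −0.5), takes the consensus
residue per aligned codon, and — where the unedited residue disagrees —
proposes the minimal C→T edit at codon positions 1–2 whose translation
matches the consensus, accepted when the fraction of references supporting
that residue reaches the cutoff (default 0.5). Predictions are
deterministic given inputs. Silent edits (position-3, or
position-1 edits like CTA→TTA that preserve leucine) are invisible to any
protein-comparison method and are excluded from recovery claims.

## Repeats

*SSRs.* Perfect runs only (MISA with no interruption parameter), per-unit
minima `1-10 2-5 3-4 4-3 5-3 6-3`; a run whose motif is a repetition of a
shorter motif is reported at the shortest unit, and contained reports are
deduplicated. The canonical class is the lexicographic minimum over
rotations of the motif and of its reverse complement, rendered with the
minimum rotation of the representative's reverse complement as the second
half (`AGC/CTG`, `AT/AT`) — the rendering that matches the published class
tables. Circular chromosomes are scanned with an appended origin-spanning
window, wrap duplicates removed.

*Tandem arrays.* For each candidate period p (7–120 by default) the
sequence is compared to itself at lag p; exact-match seed runs (≥ 7) are
extended by X-drop under the tandem-repeats-finder weights (match +2,
mismatch −7). An array must span ≥ 2 copies, score ≥ 50 over the full
array (lag matches plus one definitional period), and have match fraction
≥ 0.68. Overlapping period reports merge to the smallest valid period: the
doubled period of any array also passes the filters and would otherwise
mask the primitive unit. Copy numbers are reported to one decimal.
Substitution-only arrays are detected exactly; arrays whose copies differ
by indels shift the lag register and are found only if a sufficient
in-register stretch remains.

*Dispersed repeats.* Seeded self-comparison of every chromosome pair, word
size 7, both strands; forward = same strand, palindromic =
reverse-complement match. The trivial self-diagonal, mirrored duplicates,
same-chromosome hits whose intervals abut within 10 bp (tandem-like), and
hits covering a detected tandem array are removed. Defaults: length ≥ 27,
identity ≥ 0.90, E ≤ 1e-5.

## DNA transfer

Fragments between genome pairs pass identity ≥ 0.70, length ≥ 30 bp and
E ≤ 1e-5 ("matching rate" is read as alignment identity, the standard
BLAST-filter usage). Coverage is merged on the query (mitochondrial) axis
so nested or duplicated subject hits never double-count; the unmerged sum
is also reported since published "combined lengths" do not always state
which was used. Gene containment requires the full gene span inside a
single merged region and reports the best identity among overlapping
fragments. Nuclear chromosomes stream one at a time, keeping memory
constant in chromosome count.

## Ka/Ks and π

Nei–Gojobori site counting keeps S + N = 3 per codon by counting mutations
to stop codons as nonsynonymous; pathway averaging over d! substitution
orders excludes orders passing through a stop unless all are blocked.
Jukes–Cantor correction d = −¾ ln(1 − 4p/3) is undefined at p ≥ ¾; such
results carry a `jc-correction-undefined` flag and the uncorrected
proportions. NG86 was chosen over ML variants because it is deterministic
and checkable against an exhaustive enumeration oracle. Trailing stops are
stripped; an internal stop excludes that codon column with a warning. π
uses pairwise deletion by default (each pair compared over its own clean
sites), with complete deletion as an option; the two agree on gap-free
alignments.

On neutral simulations the NG86 ratio is mildly conservative (≈ 0.95 on
average): stop-creating mutations count as nonsynonymous opportunity but
codons containing stops are excluded from the observed counts. A single
10 kb replicate has Poisson-level spread of roughly ±0.1 around that mean,
so the reproduction script reports the mean over ten replicates.

## Synthetic study system

The generator emulates the analysed genome class: 19 circular chromosomes
of 22–48 kb at 44% GC by default (configurable), i.i.d. background bases at
the GC target, planted in-frame genes (ATG start, no internal stop, random
stop codon), planted SSRs/tandem arrays/dispersed pairs/transfer inserts
with pinned flanking bases so perfect runs end exactly at the recorded
coordinates, C→U edits restricted to nonsynonymous position-1/2 changes
that do not create stops (the recoverable class), and substitution-only
long reads (mean 10 kb, 5% error, depth 20× by default; optional indels)
with per-read origin labels. Same configuration and seed give byte-identical
outputs.

Test fixtures use 4–10 chromosomes of 20–31 kb (~100–300 kb genomes) so
the whole suite runs in minutes on one CPU; detection scales linearly in
genome length, so the choice affects runtime, not semantics. Planted
feature identities are placed strictly inside the screening thresholds
(e.g. dispersed copies at 0.93–1.0 against a 0.90 screen): a feature at
exactly the threshold is classified either way by the handful of flank
columns a maximal-scoring alignment legitimately includes, so
threshold-exact recovery is statistically ill-posed rather than a detector
property.

What passing tests show: the detectors recover what they are defined to
detect, at the stated thresholds, on composition-realistic sequence, and
the statistics agree with independent oracles. What they do not show:
robustness to structured real-genome features absent from the i.i.d.
background (true repeat families, chimeric reads, instrument-specific
error profiles, heteroplasmy), or agreement with the exact hit lists of
specific external tool versions (BLASTN, TRF, PREP dialects), whose
tie-breaking and redundancy rules differ in undocumented ways. Counts
that depend on downloaded accessions or those dialects (total repeat
counts, fragment counts on the real genome, Nc of the real CDS set) are
therefore not asserted; the published summary-table reproductions and the
method-level properties stand in for them.

## Degenerate inputs and errors

Empty codon tables, empty candidate sets, alignments with < 2 sequences,
out-of-range fragments, non-C→T "edits", unknown stop codons and
infeasible planting plans raise `ValueError` naming the offending object.
Internal stops warn and exclude the affected codon. Empty read or target
sets yield empty match lists, and an empty repeat-record set summarizes to
an all-zero table.
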