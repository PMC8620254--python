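# Methods

This note records the models, defaults and numerical choices behind each
module, what the synthetic generator does and does not emulate, and the
known limitations. Coordinates are 0-based half-open everywhere; one root
seed drives all randomness, with per-operation child streams derived from
stable key strings (`phylopop._rng.child_rng`) so any module can be
re-run in isolation and reproduce its inputs exactly.

## Read recruitment

The recruiter emulates minimum-identity fragment recruitment at desk
scale. Exact k-mer seeds (default k = 21, taken at non-overlapping
offsets plus the read tail) nominate candidate diagonals on the
reference; every candidate is scored ungapped (vectorized byte
comparison), and the read is reported once, at its best-identity ungapped
placement. Ties resolve to the lowest contig rank, then the lowest
reference start, then the forward strand. Only when no ungapped placement
reaches `minid` is a gapped rescue attempted: a banded alignment (edlib)
in a window around each candidate diagonal, accepted with at most 2 gap
columns. This precedence keeps the recruiter exactly equal to an
exhaustive ungapped sliding-window search for every read that search
would accept — the equivalence the test suite asserts — while still
rescuing reads with a small indel.

Identity is matching columns over alignment columns, gap columns
included, terminal soft-clips excluded; N never matches. The identity
threshold is inclusive (`identity >= minid`). Acceptance additionally
requires the aligned span to cover 90% of the read.

Seeding at stride k guarantees every exact occurrence is found and
tolerates scattered substitutions (one error spoils at most two seeds).
At 0.5% error on 150-bp reads the probability of missing all seeds is
negligible; the recruiter is not guaranteed to find heavily-mutated reads
near the identity floor, which matches how seed-based production mappers
behave.

External alignments are ingested from SAM (pysam); identity is always
recomputed from the CIGAR against the in-memory reference, never trusted
from tags. Multi-mapping reads keep their best placement only — how the
original analyses resolved multi-mappers is not documented anywhere we
could follow, so a deterministic best-single-placement rule was chosen
and is stated here.

## Depth, relative coverage, SNPs

Mean depth is summed base depths over base count, exactly; relative
coverage is `100 × mean(region) / mean(genome)`. Both are checked against
direct summation on randomized profiles (exact equality, no tolerance).

Variant frequency uses the total allele-count depth at the position as
denominator, so deletion-spanning reads (the DEL allele) dilute
substitution frequencies. Whether such reads should be excluded from the
denominator is genuinely open; inclusion was chosen because depth and
allele counts then reconcile exactly (`A+C+G+T+DEL = depth` when no read
carries N). Thresholds are inclusive at both ends (a call at exactly 0.01
is reported, at exactly 0.9 is fixed). The low-depth flag marks calls
with fewer than 5 supporting reads in the sample at hand; the
cross-sample view (mean support across the metagenomes reporting a SNP)
lives in `snp_consistency_report`, which also labels calls by LCR
membership.

## LCR detection

The original identification of LCRs was visual, from circos plots; no
numeric cutoff exists to copy. The detector is a windowed rule: windows
of 500 bp at 100-bp steps, flagged when their mean depth falls below
`low_frac = 0.8` of the genome-wide mean; flagged positions form maximal
runs, runs closer than 500 bp merge, and runs of at least 2 kb are
reported. Contigs of a scaffold are concatenated in rank order before
scanning, so a region straddling a contig junction is one LCR; scaffolds
are never crossed. `low_frac = 0.8` sits just above the ~78% relative
coverage the deepest accessory regions reach, which makes regions carried
by ~70% of the population deliberately marginal — every parameter is
exposed. Reported boundaries are accurate to roughly one window: depth
tapers over a read length at a deletion edge, and the window mean crosses
the threshold somewhere inside that taper.

## Aggregation and differential abundance

Group summaries average per-sample percentages (not pooled counts),
with the minimum reported alongside ("at least X% of the population");
the summer/winter fold change is the ratio of group means. Differential
region depth is tested by permuting sample labels: the statistic is the
log2 ratio of group means of depths normalized by each sample's
genome-wide mean. With few samples the null is enumerated exhaustively
(all label splits; the attainable p floor for n vs n samples is
2/C(2n, n), reached by the identity split and its complement), otherwise
10,000 random permutations with the add-one correction. P-values are
BH-adjusted across regions. This permutation engine deliberately replaces
a negative-binomial Wald fit: the claims consumed downstream (fold
changes, significance at 0.05) survive the substitution, and the fit
engine itself is not part of this package's contribution.

## GC content × read depth

Contigs of ≥ 1 kb and 30–70% GC enter a 2D space of GC percent versus
log10 mean depth; both axes are standardized and clustered with DBSCAN
(eps 0.3, min_pts 5). A reproducible density clustering replaces judging
clusters by eye; the defaults are stated, not derived. Candidate clusters
must sit within 35–65% GC, under a depth ceiling of 7500× (a value tied
to the depth regime of the motivating data — meaningless elsewhere, and a
plain parameter), and contain a contig of ≥ 10 kb. Candidates are
classified against reference genomes with the fragment aligner:
`same_species` at identity ≥ 0.95 over ≥ 50% of the member length,
`divergent_relative` at identity 0.80–0.95 over ≥ 5 kb aligned span,
`unrelated` below, `unassigned` when nothing seeds. The 0.95/0.80/50%
thresholds are asserted conventions; only the ≥ 5 kb span is inherited
from the approach being reproduced.

## CRISPR arrays and virus–host networks

The array detector is a minimal tandem-repeat finder: paired identical
11-mers at a plausible period (repeat 23–47 bp plus spacer 20–50 bp)
anchor a candidate; the maximal self-match under the period shift
delimits one repeat occurrence; occurrences are walked in both directions
and boundary columns not conserved across all occurrences are trimmed
(chance matches between adjacent spacers otherwise overshoot the repeat
edge). Arrays need ≥ 3 repeats, repeats within 1 mismatch of the first;
n − 1 spacers come from n repeats. A partial trailing repeat at a contig
end is accepted and sets `at_contig_end` — arrays genuinely tend to sit
at contig ends, where assembly breaks on the repeats. The detector
assumes a uniform period within one array (fixed spacer length); real
arrays with variable spacer lengths should be supplied directly as TSV,
the supported bypass.

Spacer→catalogue matching replaces an e-value screen with a coverage
requirement: the spacer is compared full-length, ungapped, in both
orientations at candidate positions found by exact 10-mer seeds, and hits
with identity ≥ 97% are retained. For 20–50-bp queries an e-value cutoff
is effectively a near-full-length-match requirement, so nothing is lost —
except protospacers containing an indel right at the threshold, which an
ungapped comparison cannot score; they are missed, and this is the main
known limitation of the matcher. At ≥ 97% identity a 32-bp spacer admits
no mismatches (31/32 = 96.9%) while a 34-bp spacer admits one
(33/34 = 97.06%); the suite pins that boundary from both sides.

Catalogue membership of a query contig requires 100% identity across the
whole length of the shorter of query and catalogue contig, at least 1 kb,
either orientation — implemented as exact substring containment, which
makes the shorter-sequence rule symmetric by construction. Network edges
count distinct (spacer, viral contig) pairs aggregated by source systems;
host taxa come from full-length exact spacer occurrences, and a viral
cluster whose implicated hosts span more than one phylum is flagged a
generalist.

## Markers and ANI

Pairwise identity counts matching columns over alignment columns of a
global alignment (match +1, mismatch −1, gap −2, terminal gaps free and
excluded); integer percentages round half-up — both half-up and
truncation reproduce the reference values (1505 columns / 17 mismatches
→ 99%; 366 columns / 6 mismatches → 98%), half-up is used. Protein
versus nucleotide input is auto-detected from the alphabet; N counts as
a never-matching ambiguity code for nucleotides and as asparagine for
proteins. No substitution-matrix weighting: identity only, matching how
substitutions are counted as "mutations".

ANI chops the query genome into 1020-bp fragments (the ANIb convention;
fragment length and the 30%-identity / 70%-coverage keep-thresholds are
convention, not derived), aligns each with the shared seed-and-extend
fragment aligner (exact 16-mer seeds, banded gapped extension), and
reports the mean identity of kept fragments plus the alignment fraction
(kept bases over query length). Seeding is what gives unrelated sequences
an alignment fraction of ~0: without a shared 16-mer a fragment simply
does not align, the role the e-value plays in BLAST-based ANI.
`ani(A, A) = 100` exactly, for any genome.

## The synthetic generator

The generator emulates the study conditions the chain must cope with:

- a near-clonal dominant population whose phylotypes differ by accessory
  loci (planted deletions) and SNP alleles at known expected frequencies
  (the summed fractions of carrier phylotypes);
- per-sample abundance spanning two orders of magnitude across seasons
  (the packaged seasonal preset: four summer samples at 1500× vs four
  winter samples at 15×, with the accessory region in 80% of summer and
  40% of winter cells — a 2-fold seasonal shift);
- substitution-only sequencing error (default 0.5% per base) — the
  analyses downstream concern SNPs and coverage, not indel calling;
- single-end 150-bp reads, forward strand by default with a
  reverse-complement flag. Neither read length nor error profile of the
  original Illumina data is documented; these defaults are asserted.

Reads per phylotype are exactly
`round(fraction × mean_depth × accessible_length / read_length)`, where
accessible length is the phylotype's genome length after deletions;
allocation across contigs uses largest-remainder apportionment (no
multinomial allocation noise — coverage variance then comes only from
uniform start positions), and start positions are uniform per contig.

The truth object stores, per locus and sample, both the carrier
percentage (100 × carrier fraction — the textbook reading of relative
coverage) and the exact expectation of the estimator, which differs by
three small systematic terms that matter at desk-scale genome sizes:
the genome-wide mean is deflated by the planted deletions themselves;
contig interiors run slightly above the contig mean because reads cannot
start within a read length of a contig end; and junction-spanning reads
of deletion-carrying phylotypes are never recruited. All three are
computed in closed form. For SNPs the truth also carries the expected
*observed* frequency under the error model
(`f(1−e) + (1−f)·e/3`), the right target for binomial interval checks.

`simulate_depth_profile` is a coverage-level shortcut: the same read
counts and uniform starts, binned directly into a depth profile without
materializing sequences. It is used where an analysis consumes only
depth (the seasonal preset's aggregation and differential testing);
everything SNP- or alignment-shaped runs through real reads and the real
recruiter.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: assembly artifacts and chimeras,
recombination between phylotypes, indel sequencing errors, base-quality
structure, GC-coverage bias, and contaminating community context (reads
are drawn only from the focal population; recruitment specificity against
an unrelated background is exercised only by the random-catalogue and
random-spacer negative controls).

## Problem sizes

The packaged scenarios are sized so the full suite runs in about half a
minute: parameter recovery on a 60-kb reference at 300× (~111k reads),
LCR recovery on 48 kb at 100×, the seasonal preset on 100 kb at
coverage level, oracle equivalence on ≤ 12-kb references with ≤ 5,000
error-free reads, and the GC–depth scenario with 22 contigs of 12 kb.
These sizes are the package's own defaults; every one of them is a
parameter of the corresponding config function.
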