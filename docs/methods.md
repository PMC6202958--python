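# Methods

This note documents the models, parameter choices and numerical decisions
behind rhodoscan, and what the synthetic-data tests do and do not establish
about real data.

## Marker roster and normalization model

Four protein-coding markers are quantified: proteorhodopsin (*PR*, retinal
proton pump, ~250 aa), *psaA* (P700 apoprotein of photosystem I, ~750 aa),
*pufM* (reaction-center chain M of aerobic anoxygenic phototrophs, ~340 aa)
and *recA* (~350 aa), the near-universal single-copy normalizer. A marker's
normalized abundance is

    (funcAbun / funcLen) / (RecAAbun / RecALen)

with `funcLen`/`RecALen` the **profile match-column counts**. Dividing read
counts by profile length corrects for the larger recruitment window of
longer genes; dividing by the recA quantity converts the result into
genomes-per-recA-genome, i.e., roughly the fraction of genomes carrying the
marker. Values above 1 are legitimate (multi-copy genes, co-occurring
mechanisms) and are reported unclipped. Relative abundances use the
post-QC read total of each library as denominator, so the RNA:DNA ratio of a
gene is invariant to sequencing depth. Because the DNA/RNA library-wide
composition factor does not cancel in a finite marker panel, expression is
additionally reported **relative to recA** (ratio of ratios); that is the
quantity the simulator's truth tables predict as the abundance-weighted mean
expression multiplier.

## Scoring profiles

Instead of full profile HMMs, each marker alignment is compiled into a
position-specific log-odds matrix: match columns are alignment columns with
gap fraction < 0.5; the score of residue r in column c is

    log2( ((n_cr + τ·b_r) / (n_c + τ)) / b_r )

with pseudocount τ = 1 (Laplace-style; the simplest choice that keeps unseen
residues finite) and a uniform background b = 1/20 by default
(reproducibility over realism; overridable). Gaps are affine: 4 bits to open
(first gapped position), 1 bit per additional position. Reference rows
shorter than 200 ungapped residues are dropped at load time — fragments
below that length would distort curated columns. The frequency-tuning site
is supplied as an anchor (reference row + 1-based ungapped position) because
tuning-site numbering conventions differ between PR references; it is mapped
to a match-column index at profile build time.

## Recruitment

Reads are translated in six frames (standard code; codons containing N give
'X', which scores 0 bits everywhere; fragments are split at stops, fragments
shorter than 15 aa or consisting only of X are dropped). A fragment is a
candidate for a marker if it shares at least one exact 4-mer with any
ungapped reference peptide of that marker (a blast-style pre-screen that
bounds runtime), and is then Smith–Waterman-aligned to the profile. Per
read, the best (score, marker, frame) wins, with deterministic tie-breaking
by marker order PR < psaA < pufM < recA, then lower frame index; the read is
counted when the score clears the marker's cutoff. recA runs through the
identical machinery; only tree placement is skipped for it.

**Cutoff calibration.** The e-value filters of alignment suites depend on
tool internals, so cutoffs here are empirical: score `n` random background
peptides (default 20,000 of length 34 aa — the open-reading-frame length of
a ~100 bp read) and take the (1 − α) upper sample quantile, floored at 10
bits. `target_fpr` (default 10⁻³) is defined **per read**: since each read
is tested in 6 frames against each of the markers, the per-fragment quantile
is taken at `target_fpr / (6 · n_markers)` (Bonferroni). On pure-background
libraries the realized per-read false-recruitment rate measures ~1.5×10⁻³.

**Numerical shortcut.** The batch recruiter first computes the best
*ungapped* diagonal segment score (a Kadane scan, ~4× cheaper per cell) and
runs the full affine DP only when that bound reaches (cutoff + gap_open)/2.
For any alignment with at most one gap run this bound is admissible, so the
shortcut is exact there; alignments needing ≥2 gap runs to clear the cutoff
could in principle be missed, a conservative and (for substitution-only
reads) practically irrelevant case. The operation-level `align_to_profile`
always runs the exact DP and is verified against exhaustive enumeration.

## Leaf placement

Maximum-likelihood read placement is replaced by a nearest-leaf rule that
reproduces the leaf-level assignments the downstream quantities use: per
leaf, identity = matches/compared over profile match columns inside the
read's aligned span where at least one of read and leaf holds a residue (a
read gap against a leaf residue is a mismatch; double-gap columns are
skipped). The best leaf wins if ≥ 20 columns were compared and its identity
beats the runner-up by ≥ 0.01; otherwise the read is UNPLACED — the analogue
of discarding reads that would sit on internal nodes. Cluster fractions are
computed over placed reads only; leaves absent from the cluster map count as
"other" with a warning.

## Evenness, tuning and statistics

Shannon evenness uses natural logs: J = H / ln S over categories with
positive counts; J is undefined for S ≤ 1. Evenness is computed at cluster
resolution and, within the SAR11 cluster, at leaf resolution (the scale at
which the gene-vs-transcript evenness contrast is sharpest).

Tuning-site classification: only reads whose alignment covers the FTS with a
residue count; glutamine (Q) → blue, leucine/methionine (L/M) → green, other
residues (rare) are tallied but excluded from the blue fraction. The
low-chlorophyll trend is OLS of blue fraction on ln(Chl-a) restricted to
samples with Chl-a < 0.25 µg L⁻¹ (the threshold separating blue- from
green-dominated regimes; configurable); samples at or above the threshold
are summarized by their mean blue fraction, not modeled. The fit is on the
fraction scale; percentage presentation is formatting.

The paired one-sided t-test (μ = 0) and the paired Wilcoxon signed-rank test
are implemented from their textbook definitions (scipy supplies only the
distribution functions); the signed-rank test drops zero differences, uses
the exact convolution null for n ≤ 25 without ties and otherwise a normal
approximation with tie and continuity corrections. (A "paired rank-sum
test" is a contradiction in terms — rank-sum tests compare independent
groups; the *paired* signed-rank test is what comparing gene vs transcript
evenness within samples calls for.)
Spearman correlations are corrected by Benjamini–Hochberg within whatever
pair family the caller declares (which variables form the family is a user
decision, not hard-coded). Degenerate inputs (zero-variance differences,
constant variables) are flagged, never silently dropped.

## Synthetic communities

The generator emulates the community structure the estimators assume. Per
marker, a random ancestor protein is mutated per taxon at a configurable
divergence (default 0.1; ≥ 0.5 is rejected as placement becomes
meaningless), the PR tuning residue is forced to each taxon's specification,
and genes are back-translated with uniform codon choice. The reference
alignment is the gapless alignment of the equal-length variants (a marker
with a single carrier gets the ancestor as a second row); the PR tree is
single-linkage clustering on pairwise protein identity.

Reads are drawn **jointly**: background with probability
`background_fraction` (default 0.8, so specificity is actually exercised),
otherwise source gene g of taxon t with probability ∝ abundance_t · len_g
(DNA) or abundance_t · len_g · expression_tg (RNA). This is the
equal-effective-genome-size model under which the recA normalization is
consistent; per-taxon gene-pool normalization would bias the estimator when
gene complements differ between taxa. Errors are substitutions only; both
strands are emitted; libraries are single-ended (metagenome forward reads /
merged metatranscriptome reads are the intended real-data analogue; merging
itself is out of scope). RNA reads come from the same sequences as DNA
reads — appropriate for the prokaryote-dominated < 1 µm fraction.

The **default study community** fixes the conditions used by the acceptance
script and several tests: PR in 90% of genomes split over SAR11 (35% of the
PR gene pool across six leaves with uneven expression), Gammaproteobacteria
(20%), other Alphaproteobacteria (16%), environmental clades (15%) and rare
viral/archaeal/other-rhodopsin leaves; a cyanobacterium carrying psaA (8% of
genomes) and one gammaproteobacterium carrying pufM (~11%); recA everywhere.
Expression multipliers put the community-mean RNA:DNA ratios at 26.2 (PR),
11 (psaA) and 0.013 (pufM) relative to recA, SAR11 at 52% of PR transcripts,
and SAR11 leaf-level evenness at 0.80 (genes) vs 0.57 (transcripts). The
blue/green split of the non-SAR11 leaves is a per-sample parameter, so one
shared reference set serves samples with different tuning compositions.
Defaults: 100–150 bp reads, 0.5% substitution error.

What the simulator does **not** model: indels and quality-dependent errors,
paired-end structure, strain-level microdiversity within a leaf, chimeras,
genuinely novel (out-of-reference) marker variants, variable genome sizes,
rRNA/intergenic transcriptional background structure. Passing recovery tests
therefore demonstrate estimator correctness under the stated sampling model,
not robustness to every artifact of real libraries. One consequence visible
in the acceptance output: marker–marker RNA:DNA ratios whose true value sits
below the false-recruitment floor (pufM at 0.013) are estimated at their
detection floor (~0.02–0.2 depending on depth), preserving the orders-of-
magnitude ordering but not the exact value.

## Problem sizes and determinism

Recovery tests use 50,000-read libraries (10–20 seeds per criterion) and the
acceptance study uses 80,000 DNA / 40,000 RNA reads per sample across nine
samples — sizes at which multinomial noise on every reported quantity is a
few percent and a full run stays in the minutes range on a single CPU. All
randomness flows through numpy Generators seeded from the run seed via
`SeedSequence` (reference generation, cutoff calibration and each sample ×
library get distinct derived seeds below 2³¹); seeded runs are byte-identical
on rerun, and the run log records seed, parameters and library versions.
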