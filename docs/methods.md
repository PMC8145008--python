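# Methods

This note documents the models, conventions and numerical choices behind
`viromedeck`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Count-table standardisation

A `CountTable` holds a taxa × samples integer matrix, per-sample metadata
(role `specimen`/`negative_control`, host, habitat, `total_cleaned_reads`)
and optional per-taxon metadata (family, host class, summed contig length in
kb).  Relative abundance is always `count / total_cleaned_reads`, i.e. the
denominator is the full post-QC library, not only the virally classified
fraction — sample libraries are sequenced to different depths and the
cleaned-read total is the one quantity defined identically for specimens
and blanks.

**Abundance threshold** (`abundance_threshold`, default 1/10,000,
dimensionless relative abundance).  A specimen cell survives only if its
relative abundance is *strictly* above the threshold; one read in a
10,000-read library is exactly at the boundary and is removed.  The
threshold is applied to specimen columns only: zeroing blank columns first
would destroy the very evidence the next filter needs.

**Negative-control subtraction.**  For every taxon with at least one
nonzero blank count, the comparator is the *maximum* abundance across
blanks (a conservative reading when several blanks contain the taxon), and
a specimen cell is zeroed when its abundance is equal or inferior —
inclusive, since a specimen indistinguishable from a blank carries no
evidence of genuine presence.  The comparison basis is relative abundance
by default (`control_comparison_basis="relative"`); `"raw"` is available
for equal-depth designs.  Both filters only zero cells; a taxon row
disappears only if it becomes all-zero.  Because abundances are always
evaluated on the original `total_cleaned_reads`, applying the
threshold-then-subtract pipeline twice equals applying it once.

The filter order (threshold, then control subtraction) follows the order
in which surveys list the two corrections; with the threshold restricted to
specimen columns the two commute on all but pathological tables.

**Per-kb normalisation.**  `RPK(s,t) = count(s,t) / contig_length_kb(t)`
with the length being the *summed* length of the taxon's contigs.  A zero
count is 0 regardless of length; a nonzero count with missing/zero length
is an error.

**Presentation matrices.**  The heatmap matrix is
`log10(count + pseudocount)` with pseudocount 1 so zero maps to 0.  The
classified fraction is per-sample `classified / total_cleaned_reads` with
min/mean/max summaries.  `plant_equivalents(n_samples, individuals)` is the
product of its arguments, encoding the one-larva-one-plant assimilation
used to express pooled-herbivore screening effort in plant units.

## Accumulation curves

Sample-based rarefaction on the incidence matrix (presence = count > 0,
taken *after* standardisation by the pipeline; curves on raw tables can be
requested through the library).  The exact estimator is the hypergeometric
closed form

    E[S(k)] = Σ_i ( 1 − C(N−n_i, k) / C(N, k) ),

with `C(a,b) = 0` for `a < b`, computed in exact integer arithmetic
(`math.comb`), and is the reference; the permutation estimator averages
running richness over `n_perm` seeded random orderings and additionally
reports the plain standard deviation across permutations (no
finite-population correction).  At `k = N` both equal observed richness
exactly.  `plateau_check` calls a curve asymptotic when its final increment
is at most the tolerance (inclusive), defaulting to 0.

## Reciprocal confirmation and binning

Forward hits (viral-only database) are filtered at `e < 10⁻⁵`, reverse hits
(comprehensive database) at `e < 10⁻³`; both cutoffs strict.  The best hit
per query is the lowest e-value, ties broken by the highest bit score, then
the lexicographically smallest subject id — fully deterministic.  A contig
is confirmed iff its best reverse hit passes the cutoff *and* its taxonomy
label's top-level token is `Viruses`; a cellular best hit rejects it.  A
contig with no reverse hit at all is retained but flagged
`unconfirmed-no-reverse-hit`: the reciprocal search removes candidates that
are positively contradicted, and silence is not contradiction (a genuine
cellular homolog would be found by the comprehensive search).  Family
binning sums contig counts per family and conserves read totals; an
unmapped contig is an error unless explicitly allowed.  When a contig's
forward hits span several families, the best forward hit's family is used.

## Consensus calling

Reference-guided, substitution-only: the consensus always has the
reference's length, and indels are outside the model.  At each pileup
position with depth ≥ `min_depth` (default 5, inclusive) whose majority
base differs from the reference, the majority base is emitted and a variant
recorded (position, ref, alt, depth, alt fraction); low-depth, concordant
and uncovered positions keep the reference base, the last flagged
`no_coverage`.  "Differs from the reference" is judged on the majority
base, not on any single discordant read — single-pass consensus semantics.
Majority ties keep the reference when it participates; a tie among
non-reference bases takes the lexicographically smallest and flags the
variant `ambiguous`.  Raising `min_depth` can only remove variants, and an
unreachable depth reproduces the reference exactly.  The pileup is taken as
final; iterative remapping belongs to the upstream aligner, not here.

## Sequence algorithms

**Global alignment** is an affine-gap Needleman–Wunsch (Gotoh) with three
layers (match, gap-in-a, gap-in-b); a gap of length L costs
`gap_open + L·gap_extend`.  Defaults: nucleotide match +2 / mismatch −3,
open 5 / extend 2; amino-acid BLOSUM62 with open 11 / extend 1.  The
traceback prefers match over gap-in-b over gap-in-a at ties, so the
reported alignment is deterministic.  The implementation is validated in
the test suite against full path enumeration (short pairs), an independent
memoised recursion (pairs to length 8) and Biopython's `PairwiseAligner`
scores.

**Percent identity** defaults to an SDT-like convention: terminal-gap
(overhang) columns are excluded, internal gap columns count as mismatched
columns; `exclude_gaps` and `include_gaps` policies are switchable because
the convention of the original visualisation tool is not documented.
`identity_matrix` is symmetric with a 100.0 diagonal by construction.

**ORF scan**: six frames, ATG start, in-sequence stop, length (stop codon
included) strictly greater than the cutoff (default 300 nt, so a 300 nt
ORF is excluded), and only the 5′-most start per stop codon.  Minus-strand
ORFs are reported in plus-strand coordinates.  `cds_completeness` flags
`near_full` only strictly above 0.9 and clamps recovered > reference to 1.0
with a warning.

**In-silico PCR**: the forward primer is matched on the plus strand, the
reverse primer as its reverse complement, with IUPAC degeneracy matching by
code-set intersection and an optional mismatch budget.  Primer positions are
the primers' 5′ ends (the reverse primer's 5′ end being the rightmost base
of its site).  Two lengths are reported deliberately: `region_length =
rev_start − fwd_start` — the convention under which a pair named
8007F/9134R targets a 1127 nt region — and the inclusive `product_length`
(one more).  Coordinates are 1-based inclusive throughout the package,
matching primer naming.

## Species demarcation

Decision order per contig, given its identities to the closest relative:

1. whole-genome nt identity ≥ `known_isolate_floor` (default 98.0 %,
   inclusive) ⇒ `known_isolate`;
2. a family rule exists: the designated marker identity strictly below the
   family threshold ⇒ `novel_species`, otherwise `known_strain`.  For
   `capsid_or_polymerase` rules the conservative default requires *every*
   supplied marker below threshold (`both`), switchable to `either`;
3. no family rule: best marker identity below `novelty_floor` (default
   60 % aa) ⇒ `putative_novel_no_criterion`, otherwise `indeterminate`.

Shipped rules: Alphaflexiviridae (< 80 % aa, capsid or polymerase) and
Iflaviridae (< 90 % aa, capsid); every other family has no criterion unless
the user supplies a rules TSV, which overrides per family.  The two floors
bracket the identity ranges observed in the survey the package targets
(known isolates at 98.2–100 % nt, novel genomes at 36.6–57.2 % aa) and are
configurable; verdicts between the floors are reported as indeterminate
rather than forced.  `summarize_discovery` deduplicates known species by
closest relative and splits novel counts by declared host class.

## Synthetic data: what it emulates, and what it does not

`simulate_community` draws, per specimen, lognormal abundances
(μ = 0, σ = 1.5 on the natural-log scale — roughly three orders of
magnitude between common and rare taxa, the "few dominant, many rare" shape
of real viromes) for its resident taxa, normalises to proportions and
allocates exactly `reads_per_sample` (default 100,000) reads multinomially,
so specimen column sums are exact.  Default design: 16 specimens (14
insect + 2 plant pools), 3 blanks, and 9 arthropod / 11 plant-fungus / 3
phage virus families carrying the real families' names.  Insect pools can
host all three classes (plant viruses arrive trophically, phages with the
gut flora); plant pools host only plant/fungus taxa.

Contamination is modelled as inter-sample barcode leakage: each taxon
leaks, with probability `contamination_rate` (default 0.15), out of its
most abundant (donor) sample into every other column at
`intensity × donor relative abundance` before read allocation —
`contamination_intensity` (default 0.02) into specimens and
`control_intensity` into blanks (default: same as the specimen intensity).
The control-subtraction filter is mathematically guaranteed to catch a leak
only when the blank intensity is at least the specimen intensity, so the
planted-truth validations run in that regime (blank intensity 1.0); the
package reports, not hides, what happens outside it.  Blanks contain only
leaked material against an absorbing background bucket, hence are exactly
all-zero when the rate is 0.  `total_cleaned_reads` is set to
`reads_per_sample` for every library — the simulation generates only the
viral fraction, so classified fractions are not emulated.

`simulate_contig_and_pileup` plants `n_mutations` substitutions on a random
reference; a chosen fraction of them receives depth strictly below the
consensus threshold (1–4) and the rest are guaranteed depth at or above it
(5 + Poisson), with other positions at Poisson(`depth_mean`) depth and a
per-base error rate (default 0.01) spread uniformly over the three
non-consensus bases.  `simulate_hit_tables` gives every contig a viral
forward best hit below 10⁻⁵ (a viral-only database yields spurious viral
matches even for cellular contigs) and, in reverse, a viral best hit below
10⁻³ for genuinely viral contigs versus a strong cellular best hit for
planted false positives.

Not emulated: read-level data (FASTQ, quality, assembly), chimeras, indels
and strand bias in pileups, taxonomic mis-binning between families, depth
variation between libraries, and genuinely shared taxa between host
classes beyond the residency rules above.  Passing the planted-truth suites
therefore demonstrates the correctness of the filters' logic under the
stated contamination model, not their sensitivity/specificity on real
libraries, where leak intensities are unknown and blanks may under-sample
contaminants.

## Problem sizes and determinism

Every generator and the permutation estimator take explicit integer seeds
(NumPy `default_rng`); identical seeds give byte-identical outputs, and the
pipeline manifest records seeds, versions and parameters.  The validation
suites use desk-scale sizes chosen to make their oracles exhaustive or
near-exact: 6 × 8 incidence matrices (64 subsets enumerable) for
rarefaction, sequence pairs to length 8 against an independent recursion
for alignment (full path enumeration to length 5), 1–2 kb contigs with
~100 planted substitutions for consensus calling, and ~20-taxon,
~100,000-read communities for decontamination.

## Known limitations

* The consensus caller cannot represent indels or mixed sites; it is a
  faithful but minimal reading of the depth-≥5 substitution rule.
* Demarcation requires the caller to have identified the marker proteins;
  the package does not locate capsid/polymerase ORFs automatically.
* Multiple alignment and phylogenetic placement are out of scope; identity
  is pairwise-global only, which can differ from MSA-derived identity on
  highly divergent pairs.
* The control-subtraction guarantee is conditional on blanks receiving
  contamination at least as intensely as specimens; designs with cleaner
  blanks will under-remove, which the simulation can quantify but not fix.
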