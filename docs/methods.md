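# Methods

This note records the models, conventions, and design choices behind
`stemscan`, in the spirit of the methods documentation that accompanies
simulation and statistics packages: what is computed, under which assumptions,
and what the synthetic benchmarks do and do not demonstrate.

## Structural classification

**Coordinates and alphabet.**  All positions are 1-based, fully closed
intervals, matching the display convention of tRNAscan-SE, whose "-ss" and
".out" text dialects the readers accept.  T is normalised to U for every
sequence comparison; output preserves the input alphabet.

**Pair map and helices.**  The `>`/`<` structure string is stack-matched into
a properly nested pair set.  Helices are maximal runs of stacked pairs
tolerating at most one single-nucleotide bulge per strand; a second bulge on
the same strand splits the helix.  The one-bulge tolerance keeps arm
assignment unambiguous while still absorbing the common single-bulge stems.

**Arm assignment.**  The acceptor is the outermost helix; the anticodon stem
(AS) is the helix whose innermost pair most tightly encloses the anticodon
triplet; the D-stem is the first helix 3' of the acceptor 5' strand that is
not the AS; the T-stem is the last helix before the acceptor 3' strand; any
helix between AS and T-stem is the variable stem.  A record with no helix
enclosing its anticodon is classified `OTHER` and flagged.

**AS binning.**  The bin-defining length is the bulge-inclusive span — the
number of nucleotides between and including the outermost paired bases of a
strand — taken as the maximum of the two strand spans, so a 4-pair stem with
one bulged nucleotide spans 5 and is binned `AS5` regardless of which strand
carries the bulge.  A 4-span stem is `AS4_top` with a 7-nt anticodon loop
(AL), `AS4_bottom` with a 9-nt AL (the lost proximal pair widens the loop by
2 nt), and `AS4_other` otherwise; `AS4_other` is never *Blastocrithidia*-like.

**Canonical positions.**  Position 9 is the second nucleotide after the
acceptor 5' strand (UNKNOWN when the acceptor-to-D-stem linker has fewer than
two nucleotides); 24 is the partner of the second D-stem 5' nucleotide
(UNKNOWN for D-stems under 2 bp or when that position is bulged); 27/43 are
the outermost AS pair for a 5-bp stem, or the unpaired bases immediately
outside the outermost pair for a top-unpinned stem.  The A9C and G24A flags
are identity checks at the mapped positions (C at 9, A at 24); no consensus
alignment is attempted.  UNKNOWN positions make the *Blastocrithidia*-like
flag false by caution, and are reported as such.

**Retention filter.**  Pseudogenes, records of undetermined type, anticodons
containing non-ACGU characters, and anticodons outside the 33–37 sequence
window are excluded, each with a machine-readable reason code
(`pseudogene`, `undetermined`, `anticodon_alphabet`, `anticodon_window`).
The window test anchors the triplet start in [33, 35]; raw sequence
coordinates are used rather than Sprinzl numbering, a deliberate and
documented choice since either reading of "positions 33–37" is defensible.

## Genome-level statistics

A tRNA *species* is an (isotype, anticodon) pair; initiator fMet and
elongator Met are distinct whenever the input labels them so.  Species below
0.1% of all retained tRNAs are "low abundance".  Stop-codon usage counts the
terminal codon of each CDS under the genome's genetic code — not a
genome-wide triplet scan — and a CDS that does not end in a stop under its
declared code is excluded from the denominator with a warning (under the
`trp_uga` code this includes UGA-terminated CDS, which that code forbids).
Percentages are reported to one decimal in TSV outputs.  Pearson correlations
carry a two-sided p computed through the t transform
t = r·sqrt(n−2)/sqrt(1−r²); zero variance in either variable is an error, not
a silent NaN.

## Hypothesis tests

* **Proportion Z-test**: pooled proportion, two-sided normal tail.  Two-sided
  is a declared choice; the sidedness of the original analysis is not
  recoverable.  A pooled proportion of 0 or 1 is an error.
* **Gated comparison**: Shapiro–Wilk on each group at α = 0.05; any non-normal
  verdict routes to the Mann–Whitney U (normal approximation with continuity
  and tie corrections, group sizes in scope being ≥ 10; a fully tied input
  returns p = 1), otherwise the pooled-variance Student t.  "Independent
  t-test" is deliberately the pooled-variance form, distinct from Welch's
  test which is provided separately (with Welch–Satterthwaite df) for the
  replicate-quantification comparisons.
* **ANOVA / effect size**: one-way fixed-effects F with df (k−1, N−k);
  Cohen's d with the pooled standard deviation.
* Distribution tails come from scipy; the statistics themselves are computed
  from their textbook formulas and cross-checked against scipy in the tests.

## Alignment and identity cohorts

The built-in aligner is a linear-gap Needleman–Wunsch (defaults +1/−1/−2,
configurable) with deterministic tie-breaking.  Identity is matching columns
over the full alignment length, gapped columns included.  Because identity
values are convention-dependent (the original analysis used MAFFT), cohort
*comparisons* are the supported output, not absolute identities.  For
multiple alignment a center-star construction is used: the center maximises
summed pairwise scores and other members merge under "once a gap, always a
gap".  Pairwise alignments inside the star are semi-global (terminal gaps
free), so a member that genuinely overhangs the family — the signature of a
mistranslated stop codon — is laid out past the reference ends instead of
being forced into spurious tail matches; this is what makes planted-extension
recovery exact.

## Reassignment validation

Genetic codes are built-ins keyed by label: `standard` (NCBI table 11
semantics), `trp_uga` (table 4 UGA→W semantics, stops UAA/UAG), plus
`gly_uga` and `met_agg` for the other reassignments occurring in scope.
Conceptual translation halts at the first stop of the declared code.  The
C-terminal-extension procedure aligns the standard-code members of an
orthogroup, requires their last five columns gap-free (conserved C-terminus
proxy, k configurable), re-aligns with the reassigned member, and counts the
target residues strictly after the reference end column.  The reference end
is the **maximum** over standard rows — the most conservative choice against
false extension calls; how the original procedure aggregated multiple
reference ends is not documented, so this is declared rather than inferred.
Truncations are reported separately and never count as extensions; the
counting threshold is ≥ 1 residue.  RF2 presence is an input flag from an
external homology search, reported but never computed here.  The verdict
logic: UGA-terminated CDS or any artificial extension contradicts the
reassignment; otherwise support requires a suppressor tRNA(UCA) or
codon-inference support of ≥ 100 consensus columns; anything else is
inconclusive.

## Decoding rules

Anticodons are written 5'→3' (positions 34, 35, 36) and pair antiparallel to
the codon (36↔codon 1, 35↔codon 2, 34↔codon 3) — stated explicitly because
reversed-display conventions are a common source of confusion.  Third-position
rules: strict Watson–Crick; wobble adds G34:U, U34:G and inosine reading
U/C/A; superwobble lets an unmodified U34 read all four bases; the extended
rule adds C34:A, licensed only on a top-unpinned 4-bp AS.  Inosine is an
input alphabet character at position 34 only; editing is not modelled.

The minimal-anticodon-set solver decomposes by amino acid (a unit barred from
reading codons of another amino acid or a stop can serve only one amino acid)
and solves each subproblem by exhaustive minimum set cover — exact at these
sizes.  Rule sets are treated as *enabling*: a tRNA under a relaxed model may
still be modified into a more restrictive reading (a modified U34 follows the
plain wobble rule even where superwobbling is available), so candidate units
are drawn from the requested model and all more restrictive ones.  This makes
the minimum non-increasing along strict → wobble → superwobble → extended;
the solver reports 61 / 31 / 23 / 23 for the standard code under its declared
constraints.  Published minimal-set figures depend on unstated assumptions
about inosine availability and misreading tolerance, so the solver's value is
reported under its own declared rules rather than asserted to match any
printed count.  The misreading constraint is toggleable.

## Synthetic data

Generators are pure functions of their seeds (numpy PCG64, fixed as the
package RNG so reruns are bit-identical and cross-language ports can document
divergence).  The synthetic tRNA is a textbook cloverleaf — 7-bp acceptor,
4-bp D-stem, 5-bp T-stem, AS of 2–7 structural pairs — with the D-loop length
adjusted so the anticodon always starts at position 34.  Unpinning is written
as a genuine mispair (rendered as unpaired dots, as a structure predictor
would): the top variant carries the C27A-style substitution leaving an A:G
mispair, the bottom variant a same-base mispair at the innermost pair.
Planted A9C/G24A substitutions go to the mapped canonical positions, with the
D-stem partner adjusted to keep the stem paired.

Synthetic genomes draw tRNA classes from a mixture (or an explicit species
plan), and CDS as random in-frame sense codons with the terminal stop drawn
as UGA at the planted fraction; `trp_uga` genomes never end a CDS with UGA
and instead plant internal UGA codons at a 2% per-codon rate, a rough
tryptophan-usage stand-in.  Orthogroups derive members from a common ancestor
by 5% per-site substitution outside a conserved 5-residue tail, with
extensions appended as W plus random residues.  Default study conditions —
the 0.1% abundance threshold, α = 0.05, k = 5 conserved columns, 100-column
codon-inference support, ≥ 10 genomes per order — follow the surveyed
procedure; condition-free choices (CDS lengths 50–300 codons, substitution
rate, genome counts in the default fixture) are fixed once at values a
genome-survey practitioner would consider unremarkable.

**What the synthetic benchmarks show.**  They exercise the full parsing →
classification → statistics chain against planted ground truth, so a pass
demonstrates internal correctness: structure strings are interpreted as
intended, the binning rules reproduce the planted architecture exactly, the
tests are calibrated (type-I error at nominal level), and the pipeline is
deterministic.  They do not emulate realistic sequence evolution, codon-usage
bias beyond stop-codon control, modified nucleotides, or tRNAscan-SE's own
prediction errors — so passing says nothing about covariance-model prediction
quality on real genomes, only about what this package does with predictions
it is given.

## Numerical and degenerate-input choices

Errors are raised (never silently absorbed) for: zero-variance correlation or
effect-size inputs, degenerate pooled proportions, groups too small for the
Shapiro–Wilk gate (n < 3), cohorts with fewer than two sequences, empty
orthogroups, and alignment of empty sequences.  Every excluded record or
skipped test appears exactly once in an exclusions/skip column with a reason
code.  The aligner breaks score ties deterministically (diagonal, then gap in
the second sequence); TSV outputs are sorted so identical inputs yield
byte-identical files.

## Problem sizes

The shipped test-suite and acceptance-script runs use: the full structural
lattice (96 combinations) at ≥ 11 seeds each (≥ 1000 tRNAs) for class
recovery; 500 families for extension recovery (lengths 1–50); 5000 and 2000
replicates for the two type-I-error calibrations; 1000 seeded tRNA sets for
coverage monotonicity; and a ~19-genome fixture for the end-to-end rerun.
These sizes were chosen to make the whole suite run in seconds on one core
while keeping binomial confidence bands tight enough for the calibration
checks.

## Known limitations

* Arm assignment presumes a cloverleaf-like topology; radically degenerate
  structures fall into `OTHER` rather than being modelled.
* Intron coordinates pass through unmodified; modified-nucleotide chemistry
  (cmo5U, k2C, ...) is out of scope beyond the inosine input character.
* The Mann–Whitney branch uses the normal approximation; exact enumeration is
  used only as a small-n test oracle.
* Absolute alignment identities differ from MAFFT's; only cohort contrasts
  are comparable across aligners.
* The command-line interface covers the survey stages; it is not a general
  tRNA annotation tool and performs no gene finding.
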