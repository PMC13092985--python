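# stemscan

Structural survey of bacterial tRNAs with shortened (4-base-pair) anticodon
stems, and of the decoding consequences predicted by the extended superwobble
rule.

## The problem

The anticodon arm of a tRNA canonically carries a 5-bp anticodon stem (AS)
closing a 7-nt anticodon loop (AL).  "Unpinning" one terminal AS base pair —
losing Watson–Crick pairing at the top (distal) pair, keeping the AL at 7 nt,
or at the bottom (proximal) pair, widening the AL to 9 nt — yields a 4-bp AS.
A top-unpinned tRNA-Trp with the CCA anticodon, lacking the A9C and Hirsh G24A
substitutions (the *Blastocrithidia*-like architecture), can read the
near-cognate UGA stop codon through a normally disfavoured C:A pair at the
third codon position.  This package provides, for anyone analysing tRNA gene
predictions at genome scale:

* a parser for the tRNAscan-SE secondary-structure ("-ss") and tabular (".out")
  output dialects, and a classifier that bins each tRNA by bulge-inclusive AS
  span (`AS5`, `AS4_top`, `AS4_bottom`, `AS4_other`, `OTHER`), maps the
  canonical positions 9/24/27/43, and flags the *Blastocrithidia*-like
  architecture;
* genome-level statistics: tRNA species abundance (low/high at the 0.1%
  threshold), terminal stop-codon usage per genetic code, and the correlation
  analyses (4-bp AS gene fraction vs genome size; deviant-AS fraction vs
  species abundance);
* the hypothesis-testing toolkit used by the survey: two-sample proportion
  Z-test, Shapiro–Wilk-gated Student-t / Mann–Whitney comparison, Welch's t,
  one-way ANOVA, Cohen's d, Pearson p via the t transform, and a built-in
  Needleman–Wunsch aligner for pairwise-identity cohort comparisons;
* a validation procedure for stop-to-tryptophan UGA reassignment: conceptual
  translation under alternative codes, CDS-end stop profiling, detection of
  artificial C-terminal extensions in protein orthogroups, suppressor
  tRNA(UCA) detection, and an evidence summary;
* a codon-decoding rule engine for strict Watson–Crick, Crick wobble
  (G34:U, U34:G, I34:U/C/A), superwobble (unmodified U34 reads all four third
  bases) and the extended superwobble rule (C34 on a top-unpinned 4-bp AS
  additionally reads A-ending codons), with coverage reports and an exact
  minimal-anticodon-set solver;
* seeded synthetic-data generators for every input (tRNA genes with controlled
  cloverleaf geometry, genomes with controlled stop-codon usage, orthogroups
  with planted C-terminal extensions), carrying planted ground truth for
  recovery testing.

## Worked example

Build a synthetic *E. coli*-like tRNA-Trp(CCA) whose top AS pair is unpinned
by the C27A substitution, and classify it:

```python
from stemscan.synthetic import TRNASpec, make_trna
from stemscan.trna_struct import classify
from stemscan.superwobble import readable_codons

sim = make_trna(TRNASpec(isotype="Trp", anticodon="CCA",
                         as_pairs=4, unpinned="top", seed=42))
print(sim.ss_block)
cls = classify(sim.record)
print(cls.as_bin, cls.al_length, cls.unpinned_pair, cls.blasto_like)
print(sorted(readable_codons("CCA", "AS5", "wobble")))
print(sorted(readable_codons("CCA", cls.as_bin, "extended")))
```

prints

```
synth.trna1 (1-75)	Length: 75 bp
Type: Trp	Anticodon: CCA at 34-36 (34-36)	Score: 81.1
Seq: ATGCCTAGAACGTGTGTGATCACGTGAATTGCTCCAGCCAATGCAAGTATTCGATGCATGAATATAGGCATCCCA
Str: >>>>>>>..>>>>........<<<<..>>>>.......<<<<.....>>>>>.......<<<<<<<<<<<<....

AS4_top 7 A:G True
['UGG']
['UGA', 'UGG']
```

The stem shows four pairs with the A:G mispair at the former top pair
(`A` at canonical position 27 against `G` at 43), the loop stays 7 nt, neither
A9C nor G24A is present — so the gene is *Blastocrithidia*-like.  Under plain
wobble rules this tRNA reads only the cognate UGG; under the extended
superwobble rule its decoding range additionally includes the UGA stop codon,
which is exactly the readthrough behaviour the architecture is associated
with.

The same flow works from the shell on a whole dataset:

```sh
stemscan simulate -o fixture --seed 11      # synthetic dataset + ground truth
stemscan run-all -i fixture -o results      # classify ... decode, all stages
```

`results/` then contains `classification.tsv`, per-genome summaries,
co-occurrence and per-order UGA-usage tests, identity-cohort comparisons,
reassignment evidence, decoding coverage, and a manifest.

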