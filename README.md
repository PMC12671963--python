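# snpriority

Composite prioritization of single-nucleotide polymorphisms (SNPs) in
microbial genomes. Variant callers such as Snippy readily produce thousands
of annotated variants per genome or metagenome-assembled genome; deciding
which of them are worth functional follow-up is the bottleneck. `snpriority`
ranks amino-acid-changing variants by combining three biologically
interpretable signals into a single 0–100 priority score:

1. **Normalized read depth** — min–max scaled variant depth across the
   dataset, `D_norm = (D_i − D_min)/(D_max − D_min)`, so support for each
   call is comparable across genes and samples;
2. **Amino-acid impact score** — the physicochemical disruption of the
   substitution, summing a normalized molecular-weight difference
   `W_diff = |W_ref − W_alt| / 130` (130 Da ≈ the Trp–Gly span of the 20
   canonical residues), a normalized Kyte–Doolittle hydrophobicity
   difference `H_diff = |H_ref − H_alt| / 9` (9 = the Ile–Arg span), and
   binary polarity- and charge-change indicators, for a total in [0, 4];
3. **Domain position match** — 1 if the mutated residue falls inside a
   UniProt-annotated functional domain of the matched protein entry, else 0
   (missing annotation scores a neutral 0, never an inferred value).

These combine with double weight on depth:

```
Final Priority Score = (2·D_norm + Impact + Domain_Match) / 7 × 100
```

The divisor 7 is the maximum achievable weighted sum, so the score spans
exactly 0–100; higher scores mark stronger candidates for downstream
characterization.

It is aimed at microbial genomics and microbiome researchers who already
have annotated variant tables and a species in mind; it does not call or
annotate variants itself.

## Input

A TSV or CSV table with (at least) four columns, as produced by a
Snippy-style annotation pipeline:

| Column | Content |
|---|---|
| `Gene` | gene symbol carrying the variant |
| `Amino_Acid_Position` | `x/y` — variation site / total protein length |
| `Effect` | substitution, e.g. `Val170Leu` (Snippy prefixes tolerated) |
| `Evidence` | variant depth: bare count or Snippy `ALT:n REF:m` string |

Extra columns are passed through to the output. Stop-codon and
non-canonical-residue rows are skipped with a logged reason; synonymous
substitutions are kept and score zero impact.

## Worked example

Generate a small seeded synthetic dataset (with a matched offline domain
fixture) and rank it:

```bash
snpriority --make-fixture 8 -o variants.tsv --seed 7 --make-domain-fixture domains.json
snpriority -i variants.tsv -s "Bacteroides uniformis" -o ranked.tsv \
    --domain-fixture domains.json --no-plots
```

The run logs `ranked 8 variants (read 8, skipped 0); top score 57.90` and
writes `ranked.tsv`, whose leading rows (selected columns) are:

```
Gene   Amino_Acid_Position  Effect      Evidence  Normalized_Depth  Amino_Acid_Impact_Score  Domain_Position_Match  Final_Priority_Score  Rank
gyrB   75/167               Ala75Tyr    459       1.0               2.0529                   0                      57.8981               1
rpoC   374/427              Trp374Ala   400       0.8218            1.1856                   1                      54.7019               2
glnA   13/132               Glu13Val    188       0.1813            3.0862                   0                      49.2676               3
ftsZ   635/1009             Lys635Met   128       0.0               2.6677                   0                      38.1101               4
```

Reading the top row: `gyrB` Ala75Tyr has the deepest support in the dataset
(depth 459 → `Normalized_Depth` 1.0), a substantial physicochemical change
(Ala→Tyr differs in weight, hydrophobicity and polarity: impact 2.05 of 4),
but sits outside any annotated domain, giving
(2·1.0 + 2.0529 + 0)/7 × 100 = 57.90. The `rpoC` variant ranks second on a
weaker depth but an in-domain position. Each run also emits four diagnostic
plots (component box plots, in/out-of-domain pie chart, score histogram,
and a depth-vs-impact scatter with the top 20 genes labeled) unless
`--no-plots` is given.

Against live UniProt, drop `--domain-fixture` and supply your species (and
optionally `--taxid` to skip name resolution); `--offline` forbids all
network access.

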