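# Methods

## Model

`snpriority` treats variant prioritization as a fixed-weight linear
combination of three per-variant features, scaled to 0–100:

```
score_i = (2·D_i,norm + I_i + M_i) / 7 × 100
```

* `D_norm ∈ [0,1]` — min–max normalized variant read depth. Normalization
  is **dataset-level** (min and max over the whole input file, not per
  gene): depth is a confidence signal and should be comparable across the
  file being ranked. A `--group-by-gene` option rescales within each
  gene's own depth range instead, but the whole-file scope is the defined
  behaviour and the default.
* `I ∈ [0,4]` — amino-acid impact: `|ΔW|/130 + |ΔH|/9 + P_change + C_change`.
  The denominators are **contractual constants**, not recomputed from the
  property table: 130 Da is the rounded natural span of free-amino-acid
  molecular weights (Trp 204.23 − Gly 75.07 = 129.16 Da) and 9 is the exact
  span of the Kyte–Doolittle hydropathy index (+4.5 Ile to −4.5 Arg). With
  the default table both normalized differences stay within [0,1]; a
  user-supplied weight table with a span above 130 Da is not clipped, since
  the fixed denominator is part of the score's definition.
* `M ∈ {0,1}` — 1 iff the mutated residue lies inside a UniProt "Domain"
  feature interval (1-based, inclusive bounds) of the matched entry.

The weighted maximum is 2·1 + 4 + 1 = 7, hence the divisor; depth carries
double weight, reflecting higher confidence in well-supported calls. The
score is strictly increasing in each component with the others fixed. A
`--weights` escape hatch changes the three weights and rescales the
denominator to the new maximum (`w_d + 4·w_i + w_m`) so the 0–100 range is
preserved.

## Assumptions

* Input variants have already passed the caller's quality filters; depth
  is used for relative ranking only, not for re-filtering.
* Protein coordinates in the input (`x/y` position strings, `Val170Leu`
  effects) are 1-based and mutually consistent; rows where the two
  disagree are skipped rather than silently trusted either way.
* The physicochemical property tables cover exactly the 20 canonical
  residues, so stop gains/losses and ambiguity codes (`Ter`, `Xaa`, `Sec`,
  `Pyl`) cannot be scored and are skipped with a logged reason.
  Synonymous substitutions *are* scoreable (impact exactly 0) and are kept
  by default; `--skip-synonymous` drops them instead.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| depth weight / impact weight / domain weight | 2 / 1 / 1 | — | defining weighting of the method |
| weight-difference denominator | 130 | Da | natural Trp–Gly span, fixed |
| hydrophobicity denominator | 9 | — | Kyte–Doolittle Ile–Arg span, fixed |
| UniProt length-match tolerance | ±2 % | relative | an unbounded "closest length" match risks scoring the wrong protein; 2 % absorbs minor isoform/annotation drift while rejecting paralogs |
| feature types counted as domains | `Domain` | — | the conservative reading of "functional domain"; active/binding sites and plain regions are excluded but selectable via `--feature-types` |
| output rounding | 4 decimals | — | file output only; full double precision kept internally |
| histogram binning | 10 equal bins over [0,100] | — | plot readability |

Residue classes: polar = {S,T,C,Y,N,Q,D,E,K,R,H}, positive = {K,R,H}
(histidine counted positive), negative = {D,E}; every charged residue is
polar. Weights are average free-amino-acid molecular weights and
hydropathies are Kyte–Doolittle, both taken from biopython's curated
tables. These class memberships are the standard textbook partition;
alternative partitions can be injected through a custom
`AminoAcidPropertyTable`.

## Degenerate and edge cases

* **Uniform depth** (`D_max = D_min`, including single-variant inputs):
  the min–max map is undefined. Every variant receives `D_norm = 1.0`
  with a warning — uniform depth means uniform, full, relative depth
  confidence, and assigning 0 would silently zero the double-weighted
  component.
* **No UniProt match** (no candidate, out-of-tolerance lengths, provider
  failure, offline with no fixture): the domain component is a neutral 0
  and the accession cell is left empty. Missing annotation can therefore
  never raise a score.
* **Ranking ties**: sorted by descending score, then higher raw depth,
  then input row order; equal scores share a dense rank. The tie-break is
  a determinism choice, not part of the scoring model.
* **Evidence field**: a bare number is used directly; a Snippy-style
  allele string (`T:21 C:0`) contributes the count of its first token,
  since Snippy lists the ALT allele first. `--evidence-format` forces
  either interpretation.

## Domain annotation providers

Annotation is pluggable behind one interface. The live provider queries
the UniProt REST API (gene + taxonomy search; entry length and `Domain`
features), retries transient failures, caches responses in memory and
degrades to "unannotated" rather than aborting. The fixture provider
serves a local JSON mapping `{gene@taxon → [entries]}` and makes the whole
pipeline runnable with zero network access — it is the mode used by the
test suite and the acceptance script. Entry selection is identical in both
modes: exact protein-length match first, then nearest length within
tolerance, ties preferring reviewed entries and then the lexicographically
smallest accession.

## Synthetic data

`generate_fixture` emulates the input contract, not any particular
organism: genes drawn from a fixed list of common bacterial loci, protein
lengths uniform in 120–1200 residues, sites uniform within each protein,
substitutions uniform over the canonical residues, and depths uniform over
a configurable range (default 5–500, the range used at the 844-variant
demonstration scale). `generate_domain_fixture` builds a matched offline
annotation set: one entry per observed (gene, protein length) pair, 70 %
of entries carrying one or two random domain intervals — microbial domain
annotation is sparse, and the mix exercises both match outcomes.

What this does **not** emulate: realistic substitution spectra
(transition/transversion bias, mutational hotspots), depth distributions
with coverage structure, co-occurring variants within a gene, or real
UniProt entries with isoform length disagreements. Passing tests therefore
demonstrate the correctness and determinism of the scoring pipeline, not
biological validity of any particular ranking on real data.

## Problem sizes and numerics

The test suite and acceptance script run the full pipeline at the
844-variant demonstration scale, sweep all 400 ordered residue pairs
exhaustively, and check domain membership on 1000 randomized interval
sets against brute-force enumeration; everything completes in seconds.
All scoring is double precision; the internal score identity (score
recomputed one-pass from raw inputs) holds to 1e−9. File output is
rounded to 4 decimals, so recomputing the score from the *printed*
component columns agrees to about 2×10⁻³ on the 0–100 scale (the rounding
of `Normalized_Depth` propagates with factor 200/7), which is the
tolerance used when validating written tables.

## Known limitations

* Domain matching is annotation-bound: no homology fallback (BLAST/Pfam),
  so poorly annotated species default to neutral domain scores across the
  board, compressing the score range toward the depth + impact components.
* Gene-symbol matching against UniProt is exact; locus tags or synonyms
  that differ from the UniProt gene name will not match.
* The 2:1:1 weighting is fixed by design; `--weights` exists for
  sensitivity analysis, not as a fitted parameter.
* VCF input is out of scope — the contract is the four-column annotated
  table produced downstream of the variant caller.
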