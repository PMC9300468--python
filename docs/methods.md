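# Methods

## The measurement model

Each cytosine of a mitochondrial tRNA is, in any one molecule, in one of
three states: unmodified C, m⁵C, or f⁵C. Across the molecule pool the
site is described by a stoichiometry triple
(f_unmod, f_m5C, f_f5C), non-negative and summing to one.

Two parallel chemistries read this out. Plain bisulfite deaminates
unmodified C and f⁵C to U (sequenced as T) while m⁵C resists, so the
protected (unconverted) fraction `p_BS` estimates f_m5C. In fCAB
chemistry, *O*-ethylhydroxylamine forms an oxime with the formyl group
first, so f⁵C is also protected and `p_fCAB` estimates f_m5C + f_f5C.
The estimator is the subtraction

```
f_m5C   = p_BS
f_f5C   = max(0, p_fCAB − p_BS)
f_unmod = 1 − max(p_fCAB, p_BS)
```

The two `max` clamps are this package's choice for handling sampling
noise that drives the subtraction negative (or `p_BS` above `p_fCAB`);
they guarantee a valid simplex point and reduce to the plain subtraction
whenever `p_fCAB ≥ p_BS`. The estimator treats the two chemistries as
independent binomial samples of the same molecule pool; it assumes both
libraries were drawn from the same biological material.

Key assumptions, all of which the simulator makes explicit:

- f⁵C converts in plain bisulfite at the same rate as unmodified C (the
  premise of the subtraction design); partial f⁵C protection in BS is
  not modelled.
- Per-molecule states are drawn independently across sites; the
  estimator is strictly per-site, so within-molecule correlation between
  sites (visible in the read matrix) does not bias it.
- No conversion-efficiency correction is applied by default. With the
  default noise parameters this inflates apparent protection by about
  one percentage point and deflates f_m5C by the false-conversion rate;
  an optional correction (`efficiency_corrected`) divides it out when
  calibrated efficiencies are available, but it is off because typical
  experiments of this design report none.

## Uncertainty

`p_BS` and `p_fCAB` get 95% Wilson score intervals. The f⁵C interval is
the normal-approximation interval of the difference of two independent
binomial proportions, clipped to [0, 1]; the unmodified interval is the
reflected Wilson interval of whichever protected fraction is larger.
These are per-site, per-condition intervals; they ignore replicate-level
overdispersion beyond what the replicate aggregation averages out.

## Alignment

Bisulfite conversion collapses the sequence alphabet: at a converted
site the read can legitimately differ from the reference. A
non-directional library presents each fragment in one of four states —
original top (OT), its complement (CTOT), original bottom (OB), its
complement (CTOB). Reads are therefore scored against every
(gene × orientation) candidate: the reference C matches read C or T in
the C→T-collapsed orientations (OT, OB), and the reference G matches
read G or A in the complementary ones (CTOT, CTOB).

Because the whole reference set is under 3 kb, the aligner is an
exhaustive affine-gap local (Smith–Waterman/Gotoh) scan, not a seeded
heuristic: match +1, mismatch −1, gap open −3, gap extend −1, a gap of
length k costing 3 + k. This is exact and bit-reproducible. Numerical
conventions:

- a read is UNMAPPED when its best score is below 0.8 × read length
  (configurable); this is a declared default, not a community constant;
- equal best scores at distinct (gene, sense-start) placements make the
  read AMBIGUOUS and it is discarded from all tallies;
- equal best scores among orientations at the same placement are broken
  deterministically OT > CTOT > OB > CTOB;
- traceback prefers diagonal, then gap-in-read, then gap-in-reference,
  closing gaps before extending them, so reported offsets are unique.

Modification calls at a sense-strand cytosine are made only from OT and
CTOT alignments, the two states that express the top-strand conversion
pattern (read C / complement G = protected, read T / complement A =
converted). OB/CTOB reads cover the same positions but interrogate the
opposite strand; they are recorded as OTHER there, and OTHER never
enters the conversion denominator. Including them as calls would mix an
uninformative, always-protected-looking signal into the protected
fraction (biasing it toward (1 + p)/2), which is why standard bisulfite
callers are strand-aware.

## Filters and aggregation

Reads shorter than 25 nt (post-trimming) are dropped. A site is
estimable only when its coverage (unconverted + converted calls)
exceeds 100 in **every** replicate of **both** chemistries — "more
than" is read strictly, and with more than two replicates the threshold
must hold in all of them. Replicates are aggregated by averaging the
per-replicate protected fractions and re-applying the simplex formulas
(`mean_of_fractions`, the default, weighting replicates equally);
`pooled_counts` instead sums counts and estimates once, weighting
replicates by coverage. Pooled counts and pooled-count intervals are
attached in both modes.

A site is called modified when f_m5C + f_f5C ≥ 0.20 in every replicate.
The 0.20 threshold is a package default chosen to sit far above the
apparent-modification floor created by incomplete conversion (≈1–2% at
the default noise levels) and far below genuinely modified sites
(≥ 90% in the presets); it is a flag parameter, not an estimate.

## Condition comparison

For each site present in both conditions the package reports
`fold_change_unmod`, the ratio of pseudocounted unmodified fractions
(0.5 added per cell of the fCAB converted/unconverted counts, keeping
the ratio positive and finite at boundary counts and equal to the plain
ratio to O(1/coverage)), `delta_f5c = f_f5C(A) − f_f5C(B)`, and a
two-sided Fisher exact p-value on the pooled fCAB
(unconverted, converted) 2×2 table — the chemistry whose converted
fraction measures the unmodified pool — BH-adjusted across all tested
sites. The BS table test is deliberately not combined in: the two
chemistries share molecules conceptually, and the fCAB table alone
carries the unmodified-fraction claim.

## The simulator

The generator emulates targeted amplicon sequencing of tRNA-length
references under both chemistries. Per molecule it draws a state per
cytosine from the site's truth triple, converts with

| event | probability | default |
|---|---|---|
| unmodified C converts (both chemistries) | `bs_conversion_efficiency` | 0.99 |
| m⁵C falsely converts | `m5c_false_conversion` | 0.01 |
| f⁵C converts in BS | `bs_conversion_efficiency` | 0.99 |
| f⁵C converts in fCAB | 1 − `oxime_protection_efficiency` | 0.02 |
| per-base sequencing substitution | `seq_error_rate` | 0.001 |

then samples a uniformly placed window (default length 70 nt, clipped
at gene ends — amplicons here are about 70 bp), presents it in one of
the four orientation states uniformly (the amplicon is double-stranded
at readout; bottom-strand cytosines carry no modification and convert
at the bulk efficiency), and writes constant-high-quality FASTQ.
Everything is deterministic given the seed, byte-for-byte. The noise
defaults are typical published bisulfite performance, not measured
values from any particular library; an ideal-chemistry mode (all
efficiencies perfect, no errors) exists for exact-recovery tests.

Default study conditions used throughout the tests and the reproduction
script: 10,000 reads per chemistry per replicate and 2 replicates,
which places per-site informative coverage around 2,500 per chemistry
on a two-gene amplicon panel and around 220 on the 22-gene set — both
comfortably past the >100 filter while keeping a full pipeline run in
tens of seconds on one CPU.

Stoichiometry presets: wild type puts C34 of the methionine tRNA at
(0.08, 0.57, 0.35) and the serine-2 tRNA variable-loop sites C47–C49 at
(0.10, 0.90, 0.00); the depleted condition moves C34 to
(0.64, 0.35, 0.01) — an eightfold rise in unmodified molecules with
f⁵C virtually absent. All other cytosines are (1, 0, 0).

What the simulator does **not** model: quality-score-dependent error,
PCR duplicates and amplification bias, adapter read-through (trimming
is assumed done upstream), partial f⁵C protection in BS, within-
molecule state linkage, and real mitochondrial sequence context — the
built-in 22-gene reference set is synthetic (tRNA-length random
sequences under real gene names, with the annotated sites placed where
the biology puts them). Passing tests therefore demonstrate that the
pipeline recovers known truth under an explicit noise model at amplicon
scale; they do not validate primer design, trimming, or behaviour on
genome-scale references.

## Degenerate inputs and edge rules

Zero coverage in either chemistry reports NOT_ESTIMABLE rather than
raising; empty FASTQs produce empty tables with a warning; gaps over
reference cytosines are OTHER; the read matrix marks positions outside
a read's aligned span NOT_COVERED; primer-region masking is available
upstream by editing the annotation set but is off by default, since the
assay's primer placement is not modelled.

## Known limitations

- The subtraction estimator's f⁵C variance is the sum of two binomial
  variances; at low coverage its interval is wide and the clamp biases
  it slightly upward near f_f5C = 0.
- The exhaustive aligner is quadratic per candidate; it is meant for
  amplicon panels (≲ few kb of reference), not transcriptomes.
- Orientation ties on fully uninformative reads (no C/G in the window)
  are broken by convention, which very slightly favours labelling such
  reads OT; their calls are unaffected.
- `mean_of_fractions` weights replicates equally even when coverage is
  unbalanced; switch to `pooled_counts` when replicates differ greatly
  in depth.
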