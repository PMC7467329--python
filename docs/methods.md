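# Methods

## Problem and model

`targetlens` turns a per-target knowledge bundle — solved structures,
detected binding pockets, ChEMBL-style bioactivity rows, disease and genetic
association scores, tissue expression levels, mouse genotype phenotypes,
publications and safety flags — into three decision aids:

1. **Eight area scores** in [0, 1] (druggability, structure, biology,
   chemistry, diseases, genetics, information, safety), each a
   sub-weight-normalized sum of *saturating indicators*
   `min(x / cap, 1)`.
2. **An MPO ranking score** combining the eight areas under signed user
   weights: `MPO = Σ|w_a| d_a / Σ|w_a|`, with `d_a = s_a` for `w_a > 0`
   and `d_a = 1 − s_a` for `w_a < 0`; zero-weight areas are excluded.
   This form is scale-invariant (multiplying all weights by a positive
   constant changes nothing), maps any score profile into [0, 1], honors
   negative weights as deprioritization, and complements exactly under a
   global sign flip when no weight is zero.
3. **A consensus-vote tractability class** from a random forest: the
   fraction of trees voting "tractable" is binned as Tractable (> 0.60),
   Challenging ([0.40, 0.60]) or Intractable (< 0.40). The binary accuracy
   decision during evaluation uses the ordinary 0.5 majority, distinct
   from the reporting bins.

## Area rules

The per-category indicator lists, caps and sub-weights live in one config
block (`scoring.DEFAULT_RULES`). Caps encode the evidence level beyond which
more of the same signal stops changing the assessment (e.g. 5 structures,
10 potent compounds at ≤ 100 nM, 200 publications); they are design
constants of this package, editable in one place. An all-empty record scores
0 in every category.

Safety needs care: the score must be 0 on an empty record (no evidence) yet
read "1 = safe". We therefore score *benign evidence*: indicators fire only
when safety-relevant data exist and look clean — benign-genotype fraction,
absence of lethal phenotypes given genotypes exist, absence of safety flags
given any safety-relevant data, and narrow high-level expression. Risk
coloring for display comes from a separate per-axis quality value
(`scoring.axis_qualities`), rendered with a linear red→green ramp
(`quality_color`).

Pockets: a pocket is *ligandable* when its detector score strictly exceeds
0.5 (reading the published "over 0.5" guideline literally; the cutoff is the
named constant `pockets.LIGANDABILITY_CUTOFF`). A target with no
own-structure pockets but a sequence-search homolog annotation inherits the
homolog's best pocket attenuated by the sequence-identity fraction — a
remote surrogate should never outscore an equally good own-structure pocket.
Homolog-derived evidence hence enters the druggability area at reduced
weight; full weight would treat a 30 %-identity homolog pocket as the
target's own.

## Ligand metrics

Selectivity entropy treats a ligand's reciprocal potencies as a probability
share: `a_i = 1/K_i`, `p_i = a_i / Σ a_j`, `H = −Σ p_i ln p_i` (nats by
default; a base-2 flag exists). Only Ki/Kd rows enter; multiple rows on one
target pool to the best potency. H = 0 means perfectly selective; `ln N`
means equipotent over N targets. Reciprocal-affinity weighting is the
standard potency-share reading; the entropy is invariant under any common
rescaling of the potencies.

CNS desirability is a sum of six two-breakpoint linear desirabilities over
MW (360/500), cLogP (3/5), cLogD (2/4), TPSA (90/120), HBD (0.5/3.5) and
pKa (8/10); breakpoints are an editable config
(`ligands.CNS_MPO_BREAKPOINTS`). The literature TPSA component is
hump-shaped (an optimum near 40–90 Å²); we model only its descending arm,
because high polar surface area is the CNS-limiting direction — a known,
documented simplification of this package.

## Tractability model

Descriptors: per-record counts and maxima (structures, pockets, ligands,
binding rows, best potency, association counts/maxima, expression breadth,
genotype counts, literature size, antibodies, safety flags) plus the eight
area scores — 26 columns, fixed order. Missing counts impute to 0;
score-like columns (chain coverage) impute to the column median.

Split: per class, `round(class_size × train_fraction)` members train
(default 0.7), shuffled by a seeded generator. On the 399 + 400 labeled
cohort this yields 559 train / 240 test. (The published construction lists
399 + 400 = 799 targets but prints a 560 + 240 = 800 split; we treat the
70/30 proportion as normative, which reproduces the 240-member test set
exactly and makes the 1-member train difference an arithmetic consequence
of the odd total.)

Forest: scikit-learn `RandomForestClassifier`, 200 trees, per-split feature
subset = √(n_features), bootstrap sampling, mandatory seed. The published
description fixes the algorithm family and the consensus scheme but not the
hyperparameters; these defaults are the library-standard choices. The
consensus vote is computed tree-by-tree (fraction of estimators predicting
the tractable class), not from averaged probabilities, to match the
"count the trees" semantics of the class bins.

## Synthetic data: what it emulates, what it does not

The generator (`synthetic.PROFILE_PARAMS`, one config block) emulates the
*shape* of harvested bundles: a `drugged` profile (≥ 1 structure, Poisson(6)
extras, Beta(4,2) pocket scores, ≥ 5 ligands with log-normal ~100 nM
potencies, rich associations, broad expression, 50–400 publications), a
`dark` profile (zero structures/bioactivities/pockets, sporadic
annotation — the minimally annotated proteome), and a `mixed` cohort
(30 % drugged / 40 % intermediate "partial" / 30 % dark, exact
largest-remainder counts, seeded shuffle).

The labeled training cohort (`make_labeled_cohort`) mirrors the published
construction: 399 positives drawn as `drugged`, 400 background drawn
half-dark/half-partial, then the 70/30 stratified split. It is a synthetic
stand-in and is cleaner than the real curated gene lists: the real
background was a random proteome sample that can contain genuinely
tractable-looking proteins, and the real positives include sparsely
annotated actionable genes. Consequently the held-out accuracy on the
synthetic cohort (~100 %) sits above the ~85 % published for the real
lists; passing tests show the pipeline's correctness and above-chance
learning, not the real-data error rate. Tests therefore assert the
construction counts exactly and a lower accuracy band, and the
permuted-label control (chance accuracy) guards against leakage.

Problem sizes in the test suite (cohort 799; 20-seed forest batteries at
n = 150, 60 trees; 1,000-draw property batteries) were chosen to exercise
every contract while keeping the default suite fast on one CPU.

## Numerical and design choices

- Ligandability cutoff comparison is strict (`> 0.5`); score 0.5 is not
  ligandable, 1.0 (the ceiling) is.
- Vote fractions 0.40 and 0.60 fall in Challenging (strict reading of
  "> 60 %" / "< 40 %").
- `best_target` ties break to the lexicographically smallest target id.
- List reports sort by MPO descending with an alphabetical gene tie-break
  (stable mergesort), so output order is fully deterministic.
- Publications sort most-recent first; undated records sort last; the
  literature worksheet caps at 500 rows (configurable).
- The "Variants/Mutants" worksheet is named `Variants-Mutants` because `/`
  is illegal in workbook sheet names.
- Expression labels are case-insensitive; an absent tissue reads as
  "Not observed" (code 0).
- Bundle ingestion ignores unknown fields with a logged warning; a missing
  `gene_name` or out-of-range score is a hard error naming the field.

## Known limitations

- No live data harvesting: bundles must be supplied (or generated); the
  BindingDB/Commercial-compounds worksheets render as headers without
  pass-through rows.
- The area rule lists approximate the original tool's unpublished rule
  tables; they are built from the documented signals and are editable, but
  absolute score values are not comparable to the original's.
- CNS TPSA desirability is monotone (descending arm only).
- The tractability model's published descriptor list and tuned
  hyperparameters are not public; results on real data will depend on both.
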