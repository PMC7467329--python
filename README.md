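# targetlens

Aggregate what is known about candidate drug targets and turn it into
decisions. `targetlens` is for target-discovery scientists triaging gene
lists: it condenses a per-target knowledge bundle (3D structures, detected
binding pockets, bioactivities, disease/genetic associations, tissue
expression, mouse genotypes, literature, safety flags) into

- **eight area scores** in [0, 1] — druggability, structure, biology,
  chemistry, diseases, genetics, information, safety — each a
  capped-indicator summary (`min(x/cap, 1)`, sub-weight-normalized);
- a **multi-parameter optimization (MPO) score** for ranking,
  `MPO = Σ_a |w_a| d_a / Σ_a |w_a|` with `d_a = s_a` for positive weights
  and `d_a = 1 − s_a` for negative ones, so negative weights deprioritize
  areas where evidence already abounds;
- **ligand metrics**: selectivity entropy `H = −Σ p_i ln p_i` over a
  ligand's reciprocal-potency shares `p_i = (1/K_i)/Σ(1/K_j)`, best-target
  assignment, and a six-property CNS desirability sum (0–6);
- a **tractability class** from a consensus-vote random forest: the
  fraction of trees voting "tractable" is binned Tractable (> 60 %),
  Challenging (40–60 %) or Intractable (< 40 %);
- three report modes: a multi-sheet **single-target workbook** (with an
  embedded radar profile), a **list-mode ranking CSV**, and a standalone
  **spider plot**.

Pockets are read from detector per-structure info files; a pocket is
flagged ligandable when its score strictly exceeds 0.5 (scores cap at 1).
A seeded synthetic-bundle generator ships with the package, so everything
runs without network or database access.

## Worked example

Rank a small synthetic cohort (no input files needed):

```bash
targetlens --mode list --synthetic 6 --profile mixed --seed 7 -o demo/
```

This trains the tractability forest on a seeded labeled cohort
(399 tractable-profile + 400 background records, 70/30 stratified split),
scores the six targets, and writes `demo/target_ranking.csv`:

```text
gene_name,mpo_score,tractability_vote_pct,tractability_class
SYN0002,0.8525,100.0,Tractable
SYN0006,0.8392,100.0,Tractable
SYN0001,0.2035,0.5,Intractable
SYN0004,0.1949,0.5,Intractable
SYN0005,0.114,0.5,Intractable
SYN0003,0.1135,0.5,Intractable
```

Rows sort by MPO descending (gene-name tie-break). SYN0002 and SYN0006 are
richly annotated, chemically enabled targets — high area scores, every tree
votes tractable; the rest carry little or no structural/chemical evidence
and fall below the 40 % vote bound. With custom signed weights
(`--weight chemistry=-100 --weight structure=100 ...`) the same cohort
re-ranks to favor, say, structurally enabled but chemically untouched
targets; `--weight safety=0` removes safety from the MPO entirely.

Single-target workbooks (`--mode single`) contain the fixed worksheet set
(Main with the embedded spider plot, Pubmed search capped at the 500 most
recent publications, Diseases, Open target association, Expression with the
3/2/1/0 level encoding, Genotypes with green = no abnormal phenotype and
red = lethal, Structure, Pockets, Binding with selectivity entropy and CNS
MPO per ligand, the dose-response/percent-inhibition/ADME buckets, and
more). `--mode plot` renders the eight-axis radar profile, wedge height =
amount of evidence, with the druggability, chemistry, genetics and safety
axes colored on a red→green quality ramp.

See `docs/methods.md` for the scoring rules, model assumptions and
limitations, and `src/targetlens/data/bundle.schema.json` for the bundle
format.

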