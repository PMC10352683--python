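# Methods

## Model overview

`fieldca` couples three layers on a toroidal square lattice whose sites
hold at most one cell:

1. **Carcinogen fields** — static nonnegative concentration grids
   `c_i(x, y) ∈ [0, 1]`, one per carcinogen, optionally gated on/off by
   a step schedule. The default shape is a Gaussian centered in the
   domain, `c(x, y) = exp(−((x−μ)² + (y−μ)²)/(2σ²))` with `μ = N/2 − 1`
   and `σ = N/15`; uniform fields and plain-text array files are also
   supported. Fields do not diffuse or deplete: exposure is treated as
   a chronic habit, not a dose event.
2. **A per-cell gene-expression network** — a two-layer perceptron with
   input `X = [c₁, …, c_C, α]` (local concentrations and cell age in
   steps), hidden layer `H = γ(W_X X)` and output
   `Y = γ(W_Y H + b)`, `γ(ξ) = ξ/(1 + νξ²)`. `Y_j` is the maximum
   expression change of gene `j` this step; the realized change is
   `z_j Y_j` with `z_j ~ U(0, 1)`. The age column of `W_X` has
   magnitude 10⁻⁷ and a per-gene, per-step Bernoulli(½) random sign —
   replication errors push expression in either direction. The bias
   `b_j` is recomputed from the current expression each step
   (+β/−β/0 for up-mutated/down-mutated/normal genes), so mutated genes
   keep drifting in their mutated direction.
3. **A stochastic cellular automaton** — seven site classes (NTC, MNTC,
   NSC, MNSC, CSC, TC, empty), Moore neighborhoods (the 3×3 block
   including the focal site), periodic boundaries. Each step applies,
   in order: the network and expression update; a genetic-instability
   stage; a phenotype-probability update; class transitions;
   dedifferentiation; one sampled phenotypic action per cell with
   fitness competition; and a scheduled excision if due.

### Gene panel

The shipped panel annotates 10 HNSCC genes. Five are tumor suppressors
(TP53, TP73, RB, TP21, TP16; promoted toward cancer by
*down*-regulation) and five oncogenes (EGFR, CCDN1, MYC, PIK3CA, RAS;
promoted by *up*-regulation). Each gene carries a per-carcinogen sign
in {−1, 0, +1} (column 1 alcohol-type, column 2 smoking-type; the
mapping is a named field, never positional), a list of phenotype
effects applying in its cancer-promoting direction, and the genes it
regulates. All derived matrices are built from these annotations:

- `W_X` carcinogen block = the sign table; age column = ±10⁻⁷.
- `W_Y[i, j]`: diagonal 0.1 + 0.1 per gene `j` regulates (TP53
  regulates all nine others, hence 1.0); off-diagonal ±0.01 when gene
  `j` up/down-regulates gene `i`.
- `R[i, j] = 1` when gene `i` regulates gene `j` (zero diagonal; 16
  directed pairs in the default panel).
- Phenotype increment matrices `U_inc = −D_inc` (4×G): a gene's listed
  effects, magnitude 10⁻⁶, placed in the matrix matching its promoting
  direction (`D_inc` for suppressors, `U_inc` for oncogenes).

Panels are loadable from a declarative YAML file
(`fieldca/data/hnscc_panel.yaml` ships the default), so non-HNSCC
panels require no code changes.

An important structural consequence of the sign table: the smoking-type
column pushes 8 of 10 genes toward cancer, the alcohol-type column only
3 — below the 4-gene mutated-cell threshold. Alcohol-type exposure
alone therefore cannot mutate a cell on any realistic horizon (the only
path is a ~10⁻⁶-per-step instability cascade), which is the mechanism
behind the smoking ≫ alcohol potency result.

### Mutation, instability, phenotype

A gene is *positively mutated* when `e_j ≥ M̄` (oncogene) or
`e_j ≤ −M̄` (suppressor), `M̄ = 0.1`; a cell with ≥ Υ = 4 such genes is
a mutated cell, and mutation status is re-evaluated every step in both
directions (NTC↔MNTC, NSC↔MNSC; CSC and TC are absorbing). During the
instability stage each directed related pair (i → j) fires with
probability 0.45: if gene `i` is positively mutated, `e_j` moves by
`u/ν` (`u ~ U(0,1)`) toward `j`'s promoting direction, otherwise toward
0 without overshooting. Each gene past threshold then applies its
increment column to `P = (p, q, a, d)` with probability 0.35; each
non-quiescence increment is offset against quiescence, and the vector
is clipped to ≥ 0 and renormalized, so `P` stays on the simplex
exactly.

### Initial phenotypes, lifespans, fitness

The initial phenotype table derives from the 10 h cell cycle, the
250 h tissue-cell lifespan and the 25,550 h stem-cell lifespan:
baseline apoptosis per step is `ā₁ = 10/250 = 0.04` (tissue) and
`ā₂ = 10/25550 ≈ 3.91×10⁻⁴` (stem), divided by the apoptotic factor
1.625 for mutated classes and by (5·1.625)² for cancer classes.
Proliferation is the class's proliferation factor (0.65 tissue, 14.75
stem) times baseline apoptosis; stem classes carry differentiation mass
`d̄·d̃ = 1.485/6`; quiescence takes the remainder, so each row sums to
one by construction (violations of [0, 1] raise at construction).
Differentiation spawns a transit-amplifying cell (TAC) of the mature
counterpart class (NSC→NTC, MNSC→MNTC, CSC→TC) that proliferates with a
+1/3 boost (taken from quiescence) until its lineage has divided Θ = 2
generations — `d̃ = 1/(2^(Θ+1) − 2) = 1/6` is the reciprocal of the six
cells a TAC ultimately produces. Fitness is
`f = w_p·p − w_a·a − w_age·(age·c̃/c̄_class) + bonus·1[CSC or TC]`
(all weights default 1): proliferation succeeds into empty sites, into
strictly less fit occupants, or — for cancer classes only — past a
fitter occupant with kill probability κ = 0.2. Quiescent cells move to
a random empty neighbor with probability 0.25; only cancer classes may
displace-and-kill while moving (probability 0.2, and against another
cancer cell only when the victim is less fit). Non-stem cells that
acquire differentiation mass through increments and sample the action
simply rest: they have no differentiation target class.

### Dedifferentiation, CSC conversion, excision

A non-stem cell (NTC, MNTC, TC) reverts to its stem counterpart with
probability 10⁻⁴ when its neighborhood has no stem cells or at least
six empty sites (both thresholds configurable; the at-least-six reading
is the default — the alternative at-most reading is exposed as a flag).
This maintains the stem-cell share of occupied tissue near its seeded
ratio. Mutated stem cells become CSCs with probability 2.5×10⁻⁶ per
step. By default unmutated NSCs are excluded from this conversion: with
the conversion applied to all stem cells, a zero-carcinogen 128² tissue
would spawn ~2.7 CSCs per 1,000 steps (1,065 NSC × 2.5×10⁻⁶ × 1,000)
and homeostasis would be impossible; a flag restores the
all-stem-cells behavior. Excision (mode `tumor`) empties every TC and
CSC plus every site within Chebyshev distance 2 of a TC; mode `field`
additionally empties every MNTC and MNSC. It triggers either at a fixed
step or a configurable delay (default 18 months; 1 month = 730.5 h,
1 step = c̃ h) after the first TC.

### Seeding and lineages

A fresh lattice is 64.5 % NTC, 6.5 % NSC, 29 % empty by exact-count
randomized rounding: each class gets the floor of its target count and
the leftover sites are assigned with probabilities proportional to the
fractional remainders, so realized counts are always within one site of
the target. Expressions start at zero; ages are drawn uniformly over
one expected lifespan per class to avoid synchronized apoptosis cohorts
(a cold-start flag zeroes them for tests). Every occupied seed site
founds a unique lineage; daughters inherit the parent's id and no class
transition ever changes it, so the set of living lineages only shrinks.
A tumor is monoclonal when exactly one lineage carries cancer-class
cells (CSC + TC by default; a flag counts TC only).

## Timeline, numerics and reproducibility

- Stages 1–6 are local to each cell and are computed in one compiled
  pass; dedifferentiation reads stem/empty neighbor counts snapshotted
  at the start of the step, so the pass is synchronous in effect.
  Stage 7 visits cells in a fresh uniform random permutation
  (Fisher–Yates) with first-actor-claims conflict resolution: a site
  that was born into, moved into, or already processed this stage is
  skipped. Ages of surviving cells increment at the end of the step;
  both mitosis products reset to age 0.
- Within a cell, the order of random draws is fixed and documented:
  G age signs, G expression draws, the instability pairs in row-major
  order of R (gate then magnitude), the per-gene phenotype gates, the
  CSC-conversion draw, the dedifferentiation draw.
- Randomness: a single master `numpy` Generator (seeded by
  `rng_seed`) drives initialization and hands each kernel invocation a
  fresh 31-bit seed; inside the compiled kernels an inline xorshift64*
  stream (splitmix64-scrambled seed) supplies uniforms. Identical
  (config, seed) give bit-identical trajectories; this was chosen over
  threading one Python-side stream through the kernels purely for
  speed (≈5 ms per 128² step on one CPU).
- The activation γ is non-monotone: it peaks at `ξ = 1/√ν` with value
  `1/(2√ν)` (5×10⁻⁴ at ν = 10⁶), below its nominal 10⁻³ bound, and
  *decays* for larger inputs. Consequently expression drifts fastest
  where the weighted input is ≈10⁻³ — for a Gaussian field, on a ring
  in the concentration tail, not at the center. This makes first
  mutations appear at ≈1,500–1,700 steps on a 128² grid with the
  printed constants, so the default `expression_scale` is 1.0; the
  scale remains configurable and is echoed into run metadata.
- Phenotype vectors are clipped and renormalized after increments and
  after class-baseline shifts; a class change rebases `P` by the
  difference of the initial-table rows (keeping accumulated
  deviations), falling back to the new class's initial row in the
  degenerate all-zero case. Lineage ranking breaks size ties by the
  smaller (earlier-founded) id. Row sums of the initial table are
  exact to ≤10⁻¹² by the telescoping construction.

## What the experiments emulate — and what they do not

All experiment inputs are generated internally; there is no external
data. The simulated tissue is a single 2-D epithelial sheet with
chronic, spatially fixed exposure. Real epithelium is layered and
vascularized; the model has no immune response, angiogenesis, telomere
dynamics, HPV input, chemical signaling, or pharmacokinetics, and the
network weights are assembled from qualitative annotations rather than
trained on genomic data. Passing tests therefore demonstrate the
internal consistency of the model's mechanisms (homeostasis, relative
carcinogen potency, excision ordering, clonality scaling), not
quantitative clinical predictions; absolute event times depend on the
annotation-derived weights and should be read as orderings.

## Experiment scales used by the test suite

The in-silico experiments run at reduced scale so the whole suite
finishes in minutes on one CPU; the scales are fixed design choices,
with seeds drawn as consecutive integers per experiment:

- **Homeostasis**: one 128² run, zero carcinogens, 1,000 steps; no
  mutated or cancer class may ever appear and the stem share of
  occupied tissue must stay within ±50 % (relative) of the seeded
  6.5/71 ratio.
- **Carcinogen potency**: five seed-pairs at 128²; the smoking-type run
  stops at its first mutated cell (cap 2,400 steps) and the
  alcohol-type run replays the same horizon; smoking must mutate in
  every pair while alcohol stays at exactly zero.
- **Dose monotonicity**: median first-mutation time at full
  concentration must not exceed that of a 3×10⁻⁴-scaled field
  (censored at 2,400 steps).
- **Excision ordering**: five paired replicates at 128² (smoking-type);
  each base run proceeds to 18 months after its first TC, then the same
  pre-excision state is excised in `tumor` and in `field` mode and each
  branch continues to recurrence (censored at 2,200 steps, recorded as
  cap + 1 — censoring can only shrink the field−tumor gap, never
  inflate it). Field removal must delay recurrence in every pair, or by
  a one-sided Wilcoxon signed-rank test at α = 0.05.
- **Clonality vs grid size**: three 64² runs (stopped 200 steps after
  the first TC) must be monoclonal in the majority; one 256² run
  (stopped 800 steps after the first TC, a reduced horizon) must be
  polyclonal.

Measured behavior at these scales: first mutated cell ≈1,500–1,800
steps (128², smoking), first CSC ≈1,900–4,600 steps with the first TC
1–4 steps later, tumor-only excision recurs in ≈500–700 steps while
field removal exceeds 2,200–2,500, and 64² grids develop their first
TC only around step 6,000 (the small carcinogen ring contains few stem
cells), reproducing the ordering that smaller domains see later, rarer,
monoclonal cancers.

## Known limitations

- The per-cell network is fixed, not trainable; one hidden layer only.
- Carcinogen fields are static in space; schedules only gate them.
- The instability and class-transition rules are re-derivations from
  prose (the closed-form update equations they paraphrase are not part
  of this package's sources), as are the fitness form and the
  class-rebase rule for phenotype vectors; each is the minimal form
  satisfying the stated monotonicities and conservation laws.
- Event-time distributions are heavy-tailed (CSC conversion is a small
  per-step probability), so replicate medians — not single-run times —
  are the meaningful observable.
- At 64² the Gaussian's effective mutation ring is small; runs at that
  size are slow to develop cancer and clonality conclusions there rest
  on three replicates.
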