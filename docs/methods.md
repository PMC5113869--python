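# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate.

## Data model

The canonical object is a species × fragments matrix of integer
abundances (species in rows), annotated per species with a feeding guild
(insectivore, frugi-nectarivore, omnivore, granivore) and a
forest-specialist flag. Incidence (presence/absence) is derived by
thresholding abundance > 0. Fragment metadata carry area (ha),
perimeter, a patch-proximity isolation index, and % closed-canopy forest
cover within 800 m; fragments are grouped into "large" and "small" by an
area threshold of 90 ha (the three large study fragments are ≥ 90 ha,
the nine small ones < 15 ha, so any threshold between 15 and 90 yields
the same grouping). All-zero species rows are rejected on construction
of a primary matrix but retained (with a warning) in group submatrices,
keeping the species universe aligned between groups; occurrence metrics
drop them internally because they are undefined for absent species.

The packaged `taita_fragments.csv` reproduces the published survey table
verbatim. One known inconsistency in the source is preserved rather than
resolved: the table lists 24 species for the largest fragment (Mbololo)
while the study's prose says 32; the table values are used throughout.

## Co-occurrence metrics

- **C-score.** Default is the Stone–Roberts mean checkerboard-unit count
  CU_ij = (r_i − S_ij)(r_j − S_ij) averaged over species pairs, with
  r the occurrence totals and S_ij the number of shared fragments. A
  `pairwise-fraction` normalization (divide each pair's term by r_i·r_j)
  is available behind a flag; the default is fixed because SES values
  are not invariant under this rescaling.
- **NODF.** For every unordered row pair and column pair: if the
  marginal totals are equal the pair contributes 0 (decreasing fill);
  otherwise it contributes 100 × (shared 1s) / (poorer line's total).
  NODF is the mean over all pairs. Because each pair's contribution
  depends only on which member is richer, the score is independent of
  input order; the conventional sort by decreasing totals is implicit.
  The implementation agrees exactly with R `vegan::nestednodf` on
  reference fixtures and with a brute-force pair enumeration on random
  matrices up to 8 × 8.
- **β_P = 1 − ᾱ/γ** with ᾱ the mean richness over all fragment columns
  of the analyzed matrix and γ the number of species occupying at least
  one fragment.

Whether the original analysis computed the C-score on incidence derived
from each resampled abundance matrix or on abundances directly is not
determinable; incidence is used here, since the C-score is defined on
presence–absence.

## Null models and inference

The proportional abundance model places all N individuals independently
into cells with probability p_i·q_j (observed row × column abundance
fractions), conserving N exactly; row and column totals are random with
the observed values as expectations. Metrics are evaluated on the
incidence of each resample; degenerate resamples (fewer than two
occupied species) are redrawn with the count logged, and the run aborts
if more than half of the attempted draws degenerate.

SES uses the ensemble mean and the n−1 standard deviation. The empirical
two-sided p is the add-one permutation estimator
2·min[(#{null ≤ obs}+1), (#{null ≥ obs}+1)]/(n+1), capped at 1, which
cannot return p = 0. Ensembles whose SD is at floating-point noise level
(≤ 1e-12 relative) are treated as constant: SES is reported as
undefined (NaN) and only the tail p is meaningful. Bonferroni correction
uses the family of all metric × guild × group × track tests in one run
(matching the joint presentation of the co-occurrence results);
the family definition is recorded in the output.

Ensemble size defaults to 1000 matrices. One root seed drives
everything: per-stage generators are derived by seed-sequence spawning
keyed by stage *name*, so results are bit-for-bit reproducible and
unchanged when stages are toggled.

## Functional diversity

Raw measurements are reduced to single axes: the dominant principal
component of the three bill measures (culmen length/depth/width), of the
three locomotion measures (wing, tarsus, tail), and of the categorical
diet and stratum scores; body mass and hand-wing index enter directly.
PCA is computed on column-standardized blocks (correlation PCA) because
the measures mix units; the axis sign is fixed by a positive loading on
the first input column. FAD is the sum of pairwise Euclidean distances
in Z-transformed trait space, with the Z-transformation recomputed
within each analyzed species pool (the guild), not globally — a flag
switches to global scaling. Five traits enter FAD (bill, body size,
dispersal, locomotion, stratum); diet is coded in the trait table but
excluded from FAD by default, matching the five-trait analysis design.

FAD cells are guild × single-trait × fragment; cells with fewer than two
present species are dropped. The reshuffling null permutes each trait
independently across the guild pool and recomputes FAD on the same-size
species set — implemented, equivalently, as drawing per-trait subsets
without replacement, which permits a fast inner loop. Cells containing
the entire guild pool are permutation-closed: observed FAD equals every
null score, and the SES is reported as exactly 0 (no deviation from
null) rather than undefined.

The general linear model fits FAD (or SES-FAD) on guild + trait + size
group + the three two-way interactions + richness + richness², with
sum-to-zero contrasts. Partial η² = SS_term/(SS_term + SS_error) uses
Type-III-style partial sums of squares obtained by dropping the term's
*columns* from the fixed full design and refitting (rebuilding the
formula would let the interaction coding absorb a dropped main effect).
A rank-deficient design (empty guild × trait × size cells) raises an
error rather than silently aliasing. The published error df (229) cannot
be reproduced exactly because the exact set of dropped cells in the
original analysis is unknown; the df structure (guild 3, trait 5 → 4 df
after contrast, size 1, …) is preserved.

## Competition bound

Candidate competitive-strength matrices have i.i.d. uniform upper
triangles mirrored as 1 − c, with diagonal 0.5 (a species ties against
itself) retained in the column normalization; the diagonal is
configurable since no convention is canonical. The stationary
distribution of the column-stochastic chain is found by power iteration
from the uniform vector (tolerance 1e-12 in L1, max 10⁶ iterations; for
reducible chains the limit from the uniform start is reported). The
best-of-k search (default k = 100,000) scores each candidate by the mean
Spearman correlation — midranks for ties; zero-variance rank vectors
score 0 by convention — between its stationary vector and observed
per-fragment relative abundances, over fragments holding at least three
of the guild's species; the aggregation over fragments is an unweighted
mean (the original text does not specify pooled vs per-fragment
scoring). Ties in the argmax break first-found, and with a fixed seed
the candidate stream is a prefix sequence, so r_C is monotone
nondecreasing in k. Guild × group cells with fewer than three usable
species raise an explicit infeasibility error (in the study data this
affects the single granivorous forest specialist).

r_C is an upper bound, not a hypothesis test: *any* community whose
abundance ranks are consistent across fragments — including a neutral
one with fixed species weights — admits a high-r_C competitive
explanation. This is why the validation battery (below) pairs the
competitive arm against neutral data with realistic, heterogeneous
fragment totals, where sampling noise erodes rank consistency.

## Scaling

SAR and species–abundance curves are fitted as OLS on natural-log scales
(log–log for power laws), which reproduces the published coefficients
from the survey table to printed precision (S = 12.4·A^0.21, r² = 0.44;
S = 3.03·I^0.30, r² = 0.92). Species density uses S_A = S/A^0.21 with
the exponent from the all-species SAR. The specialist-fraction
correlation uses ln(individuals) on the abundance axis (reproducing the
published r = −0.73; the raw-scale correlation does not). Two published
specialist regressions (1.23 ln A + 5.78 and 1.45 ln I − 0.49) do not
reproduce exactly from the table's specialist column (OLS gives
1.26/5.63 and 1.42/−0.39) — evidently fitted to slightly different
counts in the original — and are computed but not held to the printed
values.

## Synthetic data

Generator defaults mirror the study system: 69 species in guilds of
36/12/11/10 with 10/4/3/1 forest specialists, 12 fragments with the
observed per-fragment individual totals (grand total 17,531, three
large-fragment columns first). Species weights follow a deterministic
lognormal rank-abundance curve with shape σ = 1.5 (typical
bird-community unevenness); which species receives which rank is
randomized per seed.

- *neutral*: per-fragment multinomial placement over the species weights
  (mass effects only).
- *nested*: species occupy prefixes of the fragment-capacity ranking,
  with deterministic proportional fill (≥ 1 individual per occupied
  cell), so the noiseless incidence is exactly the designed one; with
  distinct marginal totals NODF = 100 by construction.
- *checkerboard*: species are paired within guilds and each pair's
  fragment sets are disjoint random splits; abundances are multinomial
  over the species allowed in each fragment.
- *competitive*: per-fragment multinomial draws from the stationary
  vector of a supplied competition chain, with optional Dirichlet
  jitter.

What these emulate — realistic dimensions, uneven abundances, uneven
sampling effort, controlled assembly structure. What they do not —
spatial autocorrelation, guild-dependent detectability, temporal
turnover, and trait–occurrence coupling; passing tests therefore
demonstrate correctness and statistical calibration of the machinery,
not ecological conclusions about any real community.

## Validation batteries

Three seeded simulation batteries validate the pipeline end to end
(`fragcomm.calibration`):

1. **SES calibration** — 200 neutral communities at study dimensions,
   1000-matrix ensembles: SES of C-score and NODF should have |mean| <
   0.15 with roughly 95% of values inside ±1.96. The generator fixes
   fragment totals exactly while the null model randomizes them, so
   perfect standard normality is not expected; mild overdispersion is
   within tolerance.
2. **Structure detection** — nested and checkerboard communities should
   give NODF SES > 1.96 and C-score SES > 1.96 respectively in ≥ 90% of
   100 replicates (observed SES run ≈ 7 and ≈ 47, far above threshold).
3. **Competition recovery** — a 6-species transitive hierarchy with
   graded advantage 0.15 (stationary abundances well separated relative
   to multinomial noise at N = 1000 per fragment across 12 fragments)
   should be recovered with best-of-100,000 r_C ≥ 0.8; paired neutral
   communities (6-species focal guild embedded in a 69-species neutral
   community with the default heterogeneous fragment totals) should
   score strictly lower in ≥ 95% of pairs. A uniform-random tournament
   is deliberately *not* used as the ground truth: its stationary vector
   is nearly flat, making the dominance order unrecoverable at realistic
   sample sizes.

Problem sizes for these batteries (200/100/20 replicates) balance the
Monte-Carlo resolution of the rates being estimated against desk-scale
runtimes; they are the package's reference configuration and are used
identically by the test suite and `scripts/acceptance.py`.

## Known limitations

- The original capture matrix (species × fragment abundances) is not
  redistributable, so the per-guild SES and r_C values of the original
  tables cannot be recomputed here; the validation batteries substitute
  property-based checks on data with known structure.
- The proportional-abundance null is conservative for mass effects but
  not a fixed-fixed (swap) algorithm; no swap-based null is provided.
- The competition bound assesses only the best achievable rank
  correlation; it does not estimate intransitivity frequency.
- GLM partial η² assumes the dropped-cell pattern encodes no signal;
  with many empty cells the design can become rank-deficient, which is
  raised as an error, not repaired.
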