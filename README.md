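# fragcomm

Community-assembly analysis for species communities in fragmented
habitats: species co-occurrence under abundance-based null models,
functional trait diversity with null calibration, a Markov-chain bound on
the explanatory power of interspecific competition, and species–area
scaling. The package was built around a study system of 69 understorey
bird species surveyed across 12 East African cloud-forest fragments
(three large, > 90 ha; nine small, < 15 ha), and ships both that study's
fragment metadata and synthetic community generators with known assembly
structure, so every stage is testable end to end.

## What it computes

**Co-occurrence metrics** on a binary species × fragments incidence
matrix:

- C-score — mean number of checkerboard units
  (r_i − S_ij)(r_j − S_ij) over species pairs; high values mean spatial
  segregation.
- NODF (nestedness by overlap and decreasing fill, 0–100) — 100 when
  poorer assemblages are perfect subsets of richer ones.
- β_P = 1 − ᾱ/γ — proportional species turnover (ᾱ mean per-fragment
  richness, γ regional richness).

**Null model.** Observed scores are compared against ensembles of
matrices resampled under the *proportional abundance* model: all N
individuals are placed independently into cells with probability
p_i·q_j given by the observed row and column abundance fractions — a
neutral-community equivalent without dispersal limitation. Significance
is reported as SES = (Obs − Exp)/StDev_Exp plus an add-one empirical
two-sided p, Bonferroni-corrected across all tests of a run.

**Functional attribute diversity.** FAD = Σ pairwise Euclidean distances
between species in Z-transformed trait space (bill shape, body size,
dispersal/hand-wing index, locomotion, foraging stratum; correlated
measurement blocks reduced to their dominant principal component). Raw
FAD is calibrated against a trait-reshuffling null and related to guild,
trait, fragment-size group and richness in a general linear model with
partial η² per term.

**Competition bound.** Pairwise competitive strengths c_ij ∈ [0,1]
(c_ij + c_ji = 1) are turned into a column-stochastic transition matrix;
its stationary distribution predicts relative abundances. Searching
100,000 random candidate matrices and keeping the best Spearman rank
correlation with observed per-fragment abundances yields r_C, an upper
bound on the variance in abundances attributable to any competitive
hierarchy (r_C² bounds the share explained).

**Scaling.** SAR power fits S = S₀·A^z by log–log OLS, logarithmic fits
for specialist richness, area-corrected species densities S_A = S/A^z,
and Pearson tests against fragment metadata.

## Worked example

```python
import fragcomm as fc

t = fc.load_taita_fragments().table          # packaged survey metadata
fit = fc.power_fit(t["area"], t["richness"])
print(f"S = {fit.s0:.1f} * A^{fit.z:.2f}, r2 = {fit.r_squared:.2f}")
r, p = fc.pearson_test(t["richness"], t["perimeter"])
print(f"richness-perimeter r = {r:.2f}, p = {p:.3f}")
```

prints

```
S = 12.4 * A^0.21, r2 = 0.44
richness-perimeter r = 0.61, p = 0.035
```

i.e. richness increases only weakly with fragment area (z ≈ 0.21), and
fragment perimeter correlates moderately with richness. A full analysis
on a synthetic community:

```python
scn   = fc.SyntheticScenario(scenario="neutral", seed=7)
comm  = fc.generate_neutral(scn)
traits = fc.reduce_traits(fc.generate_traits(scn))
frags = fc.generate_fragments(scn)
cfg   = fc.RunConfig(seed=1, iterations=1000, candidates=100_000)
bundle = fc.run_full_analysis(comm, traits, frags, cfg)
bundle.write("results/")                     # CSV twins + manifest.json
```

The same pipeline is scriptable from the shell (`fragcomm synth`,
`fragcomm nullrun`, `fragcomm compete`, `fragcomm fad`,
`fragcomm scaling`, `fragcomm run --config run.yaml`).

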