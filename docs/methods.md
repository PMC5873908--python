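# Methods

## Model

`embvsel` simulates recurrent genomic selection on a quantitative trait and
compares four truncation-selection criteria for phased candidates. The trait
is controlled by `L` bi-allelic QTL with known positions and effects — the
idealised setting in which criterion differences are not confounded with
prediction error. With B-allele dosage `x ∈ {0,1,2}` at a locus, the
genotypic value contribution is `0`, `(1+k)a`, `2a`, where `a > 0` is the
homozygous effect and `k ∈ {−1,0,+1}` the dominance coefficient. Allele
substitution effects are `α = a(1 + k(1 − 2p))` and breeding values
`g_i = Σ_l (x_il − 2p_l) α_l`, with allele frequencies `p` recomputed from
the current candidate set every cycle (so `α`, and the wGEBV weights, drift
with the population under dominance).

The four criteria:

- **GEBV** `= Σ_l x_il α_l` — the genome-wide sum; maximises single-cycle
  response.
- **wGEBV** `= Σ_l x_il ω_l α_l` with
  `ω = (π/2 − arcsin√p) / √(p(1−p))` — up-weights rare favorable alleles.
  At fixed loci (`p ∈ {0,1}`) the weight is set to 0: a monomorphic locus
  cannot respond to selection and the raw expression is undefined there.
- **OHV** `= 2 Σ_k max_j Σ_{l∈S_k} x_il^(j) α_l` over an equidistant
  partition of each chromosome into `N_S` haplotype segments — the GEBV of
  the best doubled haploid (DH) constructible under free recombination
  between segments and complete linkage within them.
- **EMBV** `= E[max of N_G DH-line GEBVs]` the candidate would contribute if
  selected, where `N_G = round(2·N_cand/N_sel)` (half away from zero,
  minimum 1) is the expected number of gametes a selected parent passes on.
  EMBV is the finite-population counterpart of OHV: it weights a superior
  gamete by its probability of actually being sampled.

EMBV is estimated by Monte Carlo: each replicate simulates `N_G` meioses,
doubles the gametes, records the maximum DH GEBV; replicates accumulate
until the empirical standard error of the mean of the maxima falls below
`se_tol = 0.01` (at least 10 replicates, capped at 10,000 with a logged
warning). The tolerance is interpreted on the trait scale after
unit-variance scaling, so it is ~1% of the founder additive SD. A normal
approximation `EMBV ≈ GEBV + E(X_(N_G)) σ_i` is also provided, where
`E(X_(n))` is the expected largest order statistic of `n` standard normals
(computed by quadrature of `n x φ(x) Φ(x)^{n−1}`, |error| < 1e-6) and
`σ_i² = Σ_{het} α² + Σ_{l≠m het} α_l α_m s_l s_m (1 − 2 r_lm)` is the exact
DH-GEBV variance given Haldane recombination fractions `r_lm` (`s_l = ±1`
encodes which haplotype carries the favorable allele).

## Meiosis

Recombination follows the Haldane model: per chromosome, crossover count
~ Poisson(length/100), positions uniform, starting strand fair, no
interference and no obligate chiasma. This is the simplest defensible
no-interference model and is the one consistent with using the Haldane map
function inside the analytic `σ_i`. Because the crossover process is
Poisson, the strand indicator along a chromosome is equivalently a Markov
chain whose switch probability between loci `d` cM apart is
`r(d) = (1 − e^{−2d/100})/2`; the vectorised mating path uses that
representation, and the EMBV kernel samples crossover events only inside
each chromosome's heterozygous span (crossovers outside it merely reshuffle
a fair starting coin). All three samplers are distributionally identical at
the loci; tests cross-check them against each other and against the map
function. An interference model (e.g. Kosambi) would change fine
quantitative details but is out of scope.

## Base population and genome

The default genome is 2,000 cM on `N_chr ∈ {5,20,40}` equal chromosomes with
1,000 equidistant QTL. The base population is built forward in time:
generation 0 draws every allele copy i.i.d. Bernoulli(0.5); 1,500
individuals random-mate for 3,000 generations; a 40-individual bottleneck
for 15 generations builds up the strong linkage disequilibrium typical of
elite plant-breeding germplasm; expansion to 5,000 individuals for 3
generations removes close relatedness. There is no mutation, so
polymorphism only decays; monomorphic loci are removed at the end. Mating
draws, per offspring, two parents uniformly with replacement (selfing
allowed) and one gamete from each, which at a single locus is exactly a
Wright–Fisher model on 2N gene copies — the heterozygosity-decay test uses
the closed form `E[H_t] = 0.5 (1 − 1/(2N))^t`.

A desk-scale preset (`reduced_base_population`) keeps the same demography
shape at 150 individuals and 300+15+3 generations. It retains roughly half
the loci as polymorphic and shows the same qualitative LD structure; all
trend tests and the acceptance script use it. Absolute gain levels shift
slightly with base-population size; criterion *rankings*, which are the
object of interest, are robust to this (they are paired within replicate).

`make_fixture_population` generates linkage-equilibrium populations with
prescribed allele frequencies for unit tests; it deliberately lacks the LD,
frequency spectrum and relatedness of the simulated base population, so
tests built on it exercise correctness of the arithmetic, not realism.

## Breeding program

Effects are drawn per replicate (`a ~ Gamma(1.66, 0.4)`, dominance signs
fair and independent of effect sizes) and rescaled once so the *base
population* has unit additive variance; founder sets (`N_cand` individuals
sampled without replacement) then define `σ_a0` and the gain scale
`R_t = (mean G_t − mean G_0)/σ_a0`. Scaling against the base population
rather than the founders keeps the scale independent of founder sampling
noise; the difference only affects `σ_a0` through sampling error. Each
cycle recomputes `p` and `α`, scores, selects the top `N_sel` (ties broken
by lower candidate index for determinism) and random-mates into `N_cand`
offspring. Diversity is tracked as `σ_at²/σ_a0²`, polymorphic-locus counts
and mean alleles per locus.

Experiments are paired: within a replicate, all criteria start from
bit-identical founders and architecture, and each program's mating stream is
keyed deterministically by the replicate index and the program
configuration's content hash — identical configurations replay identical
randomness, different criteria diverge only through their selection
decisions. Relative gain is reported as a ratio of replicate-mean `R`
curves, `100·(R_crit − R_GEBV)/R_GEBV` (per-replicate ratios are unstable in
early cycles where `R ≈ 0`), and the crossing cycle is the first cycle where
a criterion's mean `R` exceeds GEBV's and remains above it for two
consecutive cycles (the persistence requirement suppresses noise-induced
crossings).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_cand` | 50 | candidates per cycle |
| `n_sel` | 3 | selected parents (⇒ `N_G = 33`) |
| `cycles` | 50 | selection cycles |
| `gene_action` | additive | `k = 0`, or `dominant` (`k = ±1` fair) |
| `ns_per_chrom` | 2 | OHV segments per chromosome |
| `embv_se_tol` | 0.01 | EMBV Monte-Carlo SE target (trait units, `σ_a0 ≈ 1`) |
| `embv_min_reps` / `embv_max_reps` | 10 / 10,000 | replicate bounds |

The OHV segment count is a genuine tuning knob of that criterion: small
`N_S` defers gain further into the future. The package defaults to
`N_S = 2` for the standard 100 cM chromosomes and ships `sweep_ohv_ns`,
which runs the geometric grid `N_S ∈ {1, 2, 4, …}` (while segments stay
≥ 6.25 cM) and reports the `N_S` maximising mean gain at a chosen horizon —
the procedure by which an operator should pick `N_S` for their own genome
and program length. Segment intervals are half-open `[left, right)` with
the last closed; a locus exactly on a breakpoint joins the right segment.

## Numerical choices and degenerate inputs

- Variance convention: population variance (denominator `n`) everywhere —
  the candidate set is the entire population of interest.
- Monomorphic loci stay in all vectors with zero contribution; they are
  physically removed only when the base population is finalised.
- A founder sample with zero additive variance is resampled up to 10 times,
  then raises; practically unreachable at `L ≈ 1000`.
- Homozygous candidates short-circuit the EMBV kernel (every DH equals the
  candidate's GEBV; SE is exactly 0).
- Seeding: every stochastic operation takes an explicit `numpy` Generator;
  experiment streams derive from `SeedSequence(seed, spawn_key=…)`, making
  trajectory CSVs byte-stable for identical seed + base population.

## Scale of the shipped checks

The full-scale study design (5,000-individual base population, ≥ 600
replicates of 50-cycle programs) is the package default and runs overnight
on one core via the CLI. The shipped test suite and `scripts/acceptance.py`
instead use the reduced base population with 40 and 24 paired replicates
respectively — sizes chosen so the whole suite runs in minutes while the
paired sign tests retain power at α = 0.01. Consequently the suite asserts
*signatures* (EMBV overtakes GEBV between roughly cycles 3 and 10; OHV and
wGEBV lag early; diversity ordering OHV > EMBV > GEBV; positive cycle-50
relative gains for EMBV and OHV), not the full-scale percentage values,
which carry base-population and replicate-count dependence.

## Known limitations

- No mutation, no interference, no sex-specific maps, no epistasis.
- Marker effects are the true simulated effects: results bound what the
  criteria can do with perfect knowledge; estimation error in practice will
  differentially penalise wGEBV (allele mislabeling) more than EMBV/OHV.
- Phasing is assumed perfect in scoring mode; phasing error would degrade
  EMBV and OHV but not GEBV/wGEBV.
- The wGEBV weight diverges as `p → 0+`; populations carrying extremely
  rare favorable alleles make wGEBV rankings sensitive to single copies.
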