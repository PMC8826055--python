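# Methods

This note documents the models implemented in mobkit, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions that affect results.

## Methane oxidation kinetics

Headspace CH₄ depletion is modeled as linear between observations. MOP
converts the ppmv drawdown over a chosen window into a mass rate:

```
MOP [μg g⁻¹ h⁻¹] = Δppmv·10⁻⁶ · V_headspace[L] · (16 g mol⁻¹ / 22.4 L mol⁻¹)
                   · 273/(273 + T[°C]) · 10⁶ / (m_soil[g] · Δt[h])
```

i.e. the consumed CH₄ volume is converted to moles through the ideal-gas
molar volume at STP with a temperature correction to incubation conditions,
then to micrograms. Defaults describe a 120-ml serum bottle with 5 g dry
soil (≈115 ml headspace) at 28 °C. Consumption is reported positive; a net
increase yields a negative MOP with a warning. A `verbatim` mode freezes the
legacy constants (0.120 L, 301 K) used by older spreadsheets for this
protocol; it exists for comparison only. `time_to_fraction_consumed`
linearly interpolates the first crossing of the threshold concentration and
returns `None` when it is never reached.

For the nominal setup (40,000 ppmv, 90 % consumed over 5–12 days) the
formula yields ≈2–5 μg g⁻¹ h⁻¹. Published wetland-soil potentials measured
with this protocol span roughly an order of magnitude around the tens of
μg g⁻¹ h⁻¹; the kinetics tests therefore assert only a broad plausibility
band, not a point value.

## Diversity statistics

* **Rarefaction** is a single, seeded multivariate-hypergeometric draw
  (without replacement) to a fixed depth; shallower samples are dropped with
  a warning.
* **Faith's PD** is the total branch length of the subtree spanning the
  present tips and the root, computed directly on the tree (multifurcating
  roots are legitimate inputs).
* **PCoA** is classical scaling. Negative eigenvalues (non-Euclidean input)
  are dropped and the proportion explained is renormalized over the positive
  spectrum — the common convention when only the leading axes are read.
* **ANOSIM** uses the rank statistic r = (mean between − mean within)/(M/2)
  and the +1-corrected permutation p-value, so p is floored at
  1/(permutations+1).
* **Group tests**: two groups → two-sided Mann–Whitney U (exact enumeration
  when total n ≤ 10 and values are untied), otherwise Kruskal–Wallis with
  tie correction. Correlations use a permutation p-value below n = 10.
* **Differential abundance** is a deliberate simplification: Kruskal–Wallis
  on relative abundances with BH correction and the enriched group taken as
  the highest median. It makes no distributional (negative-binomial)
  assumptions and no effect-size shrinkage; treat it as a screen, not a
  replacement for model-based tools.

## Assembly null models

All phylogenetic metrics run on the cophenetic (patristic) distance matrix
of the tips shared between table and tree.

* **ses-MPD**: abundance-weighted mean pairwise distance per sample,
  standardized against `n_null` tip-label shuffles of the distance matrix;
  z < −2 is phylogenetic clustering, z > 2 overdispersion.
* **βMNTD**: `½[Σᵢ fᵢᵃ·min_{j∈b} d(i,j) + Σⱼ fⱼᵇ·min_{i∈a} d(j,i)]` with f
  the within-sample relative abundances (abundance weighting is the default
  because the pipeline operates on rarefied abundance data; an unweighted
  switch exists). A taxon shared by both samples is its own nearest
  neighbor (distance 0).
* **βNTI** standardizes observed βMNTD against the same tip-shuffle null.
  `n_null` defaults to 999 (199 in the test suite for speed). Pairs whose
  null distribution has zero spread are flagged undefined rather than
  silently scored.
* **RC_bray**: the null conditions on each sample's observed richness and
  total reads; species identities are drawn without replacement with
  probability proportional to occurrence frequency, each drawn species gets
  one read, and the remainder is filled multinomially proportional to
  pool-wide relative abundance. Per randomization one null community is
  assembled per sample and Bray–Curtis is computed among them; each pair's
  marginal null distribution is identical to per-pair resampling, at a small
  fraction of the cost. Ties in the empirical CDF count one half.
  RC = 2·(fraction of null ≤ obs) − 1 ∈ [−1, 1].
* **Classification**: HS if βNTI < −2; VS if βNTI > 2; else DL if
  RC > 0.95; HD if RC < −0.95; UD otherwise. Process fractions are reported
  over within-group pairs for a chosen grouping (site or wetland type), and
  βNTI / RC_bray are regressed on pairwise |ΔMOP| by OLS.

## Synthetic communities and what they do (not) show

The community generator is the ground truth for the recovery tests, built so
that each assembly regime produces the signature its detector looks for —
which is exactly the assumption the null-model framework itself makes
(phylogenetic signal in niches, turnover against a fixed regional pool).

Shared scaffolding: an ultrametric pure-birth tree; one log-normal (σ = 1.5)
species-abundance distribution over the 500-OTU pool; a Brownian trait on
the tree, standardized; per-sample ecological drift as a Dirichlet draw of
total concentration 300 around the regime composition; multinomial counts at
depth 1,172 (the emulated per-sample read depth); 4 sites × 9 samples.

* **Drift**: samples drift independently around the common composition.
  The concentration (300) was calibrated so that observed Bray–Curtis
  turnover sits centered in the Raup–Crick null band (RC ≈ 0) — under this
  framework that *is* the definition of drift; turnover below the band reads
  as homogenizing dispersal and above it as dispersal limitation. Recovery
  of the undominated class is stable for concentrations ≈300–1000.
* **Selection** (variable/homogeneous): Gaussian fitness
  `exp(−s/2·(trait−opt)²)` with strength s = 10 by default (s ≥ 5 is the
  detectable range; at s below that selection is too weak to distinguish
  from drift at this depth). Variable selection spreads site optima across
  ±2 SD of the trait; homogeneous selection uses the single +2 SD optimum.
  Extremes of a Brownian trait are phylogenetically clustered, which makes
  the shared filter detectable — a filter at the trait center would be
  invisible to βNTI by construction because many unrelated lineages cross
  the center. Each site additionally applies an independent log-normal
  colonization lottery (σ = 1) over the fit taxa: selection decides the
  clade, history decides which members dominate locally. Without that
  turnover, βMNTD between near-identical samples is ≈0 under both the
  observation and the null and carries no signal.
* **Homogenizing dispersal**: the per-site lottery divergence is mixed
  toward the pooled mean with weight 0.95 *after* drift, emulating mass
  effects that suppress local divergence; the result is communities far more
  similar than the null expects (RC → −1).
* **Dispersal limitation**: independent random occupancy subsets
  (probability 0.2) of the pool. This regime is generated faithfully but is
  *not* expected to be recovered as DL by RC_bray: the null's
  occupancy-frequency weighting tracks the same randomness, so the metric
  correctly sees turnover near its expectation. Detecting DL requires
  spatial structure (distance-decay) that this generator does not model.

Known limitations: trait extremes on a Yule tree occasionally live on
scattered long-pendant tips rather than one coherent clade, which makes the
homogeneous-selection signature tree-realization-dependent (recovery
hovers near the 60 % acceptance floor rather than comfortably above it);
real phylogenies with deep habitat-associated clades are an easier target.
The generator also does not model SIP fractionation physics, chimeras,
sequencing error, or spatial distance between sites.

## Network inference

The planted-truth generator builds a planted-partition support (4 modules,
within-module edge probability 0.25, between 0.02), places ±0.4 partial
correlations on edges (90 % positive, the skew typical of co-occurrence
networks), enforces strict diagonal dominance (guaranteeing positive
definiteness), draws latent multivariate normals, exponentiates, and
multinomially samples counts at depth 1,172. These defaults plant a sparse,
identifiable structure (mean degree ≈ 2) so the recovery benchmark measures
the inference rather than the benchmark's own ambiguity.

Inference follows the neighborhood-selection (MB) recipe on CLR-transformed
counts (pseudocount 1): per-node lasso regressions over a 30-value
log-spaced penalty path (data-driven maximum down to 1 % of it), StARS
stability selection with 20 random subsamples of size min(10·√n, 0.8·n) and
instability threshold 0.05, edges combined across directions by the OR rule
(switchable to AND), signed by the mean of the two directed coefficients,
refit on the full data at the selected penalty. Everything is deterministic
given the seed. On the default benchmark (n = 200, p = 40) edge F1 is
≈0.6–0.8 with precision ≈0.85; under an independence null the spurious-edge
rate is ≈1 %.

Topology conventions: betweenness is Brandes on the unweighted, unsigned
graph, unnormalized; centralization is Freeman degree centralization;
modules come from seeded Louvain on the unsigned graph, labeled by
decreasing size; Zi uses the within-module degree z-score (0 for
zero-variance modules), Pi = 1 − Σ(kᵢₘ/kᵢ)² with isolated nodes assigned
Pi = 0; role quadrants at Zi = 2.5, Pi = 0.6. Natural connectivity is
ln(mean eᵏ) over adjacency eigenvalues (computed via logsumexp for
stability); robustness curves remove 0–80 % of nodes in 5 % steps, randomly
(averaged over 50 orders) or by decreasing intact-network degree with ties
broken by node id.

## Pipeline and reproducibility

`mobkit run` derives one seed per stage from the master seed by hashing the
stage name (CRC-32, kept below 2³¹), so stages can be rerun independently.
Every output is tab-separated UTF-8 with 6-significant-digit floats; the
manifest records package version, parameters, per-stage seeds, and SHA-256
checksums of all outputs. Two runs with the same config produce
byte-identical files. The default synthetic run (36 samples, 500 OTUs,
999 null randomizations) completes in well under a minute on one CPU; the
test suite uses 199 randomizations and smaller pools where the check does
not depend on scale.
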