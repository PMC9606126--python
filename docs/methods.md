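# Methods

## The calibration problem

Fossil pollen is the main proxy for past plant diversity, but a pollen sample
integrates vegetation over an unknown surrounding area, filtered by
taxonomy (many species share one pollen type), by differential pollen
production, and by dispersal. `pollendiv` implements the modern-calibration
approach: pair pollen samples with radius-resolved plant surveys at the same
sites, compute matching diversity measures on both sides, and scan the survey
radius to find the spatial scale at which they agree best.

## Diversity measures

**Rarefied richness.** Samples differ in counting depth, and richness is not
comparable across depths. Each sample is reduced to a fixed sum by drawing
grains without replacement — a multivariate hypergeometric draw, equivalent
to shuffling the grain pool and keeping the first `depth` grains. The draw is
repeated `n_reps` times and the median per-draw taxon count is reported (a
half-integer when `n_reps` is even; never rounded). Defaults: depth 943
(the smallest sum in the motivating study design), 100 repetitions. The
exact expectation Σ_t [1 − C(N−n_t, d)/C(N, d)] is implemented separately
(`expected_rarefied_richness`) and used as the oracle in tests.

**Productivity adjustment.** Counts are divided by relative pollen
productivity estimates where available (unmatched taxa pass through raw,
flagged; matching is exact-string after trimming). Divided counts are no
longer integers, so "resampling without replacement" is undefined on them;
the package resamples multinomially with probabilities proportional to the
adjusted values (default depth 520). A `round-then-hypergeometric` mode is
provided for sensitivity analyses. Because probabilities are normalised per
site, PPE tables are only defined up to a common factor.

**Total-variance beta diversity.** For presence/absence Y, Jaccard
dissimilarity ignores joint absences: D = 1 − a/(a+b+c). The total variance
of Y follows from the Gower-centred matrix G of A = −½D∘D: SS_i = G_ii,
SS_total = ΣSS_i = (1/n)Σ_{i<j}D_ij², BD_Total = SS_total/(n−1),
LCBD_i = SS_i/SS_total. The square-root transform of D is applied by default:
√Jaccard is Euclidean-embeddable, which guarantees SS_i ≥ 0 and keeps
BD_Total in [0, 1]; a flag disables it, and both modes are exposed because
published BD values do not always state the convention. When SS_total = 0
(identical rows) LCBD is reported as undefined, never 0/0. LCBD significance
uses permutations that shuffle each taxon column independently, with
p = (#exceedances + 1)/(n_perm + 1); raw p-values are reported (no
correction across sites, matching common practice; a Holm column can be
added by the caller).

**Radius scans.** Plant-side measures are evaluated on a grid of radii
(default 0.5–1000 m, 25 radii covering every band boundary the survey design
uses); "present within r" means first-appearance distance ≤ r (closed
interval). At each radius an OLS of the pollen measure on the plant measure
is summarised by slope, R², adjusted R² (one predictor:
1 − (1−R²)(n−1)/(n−2)), and the two-sided slope p-value with a 0.05
significance mark — deliberately uncorrected across radii and therefore
anticonservative, as in the practice the package reproduces. The source area
is the radius with maximal adjusted R²; ties break to the smallest radius
(the most local interpretation), and radii with zero predictor variance are
reported with an undefined adjusted R² and excluded from the argmax. Sites
with no plant record inside a small radius contribute richness 0 rather than
being dropped.

## The synthetic landscape generator

The generator emulates a two-region calibration study: a species-poor and a
species-rich region (default pools 60/90 vs 120/160 species for
forest/open habitats, 15% habitat overlap as generalists), with the
10/11/19/20 forest/open site design. It exists to provide planted ground
truth; every pipeline stage is tested against it.

Per site, the landscape is a set of concentric annuli bounded by the scan
grid. Central bands (≤ 10 m) are pure site habitat — sites sit inside
continuous habitat — and outer bands mix in the other habitat with weight
`mosaic_grain · U(0,1) · √(r/1000)`, so the mosaic appears with distance;
the rich region has the finer grain (0.30 vs 0.15).

Species have log-normal commonness (σ = 1.2) and per-(site, species)
log-normal patchiness (σ = 1.0) representing spatial aggregation; patchiness
is what generates compositional turnover between sites. A few canopy
dominants per region (3 species holding 70% of the forest pool's abundance
mass, exempt from patchiness) emulate plantation/oakwood canopies. Band
occupancy is Bernoulli with rate 1 − exp(−commonness · patchiness ·
habitat weight · band intensity). Band intensities are normalised so a
median species of the focal habitat appears within 10 m with probability
`fine_scale_richness` (0.30) and grow with the surveyed area as a sub-linear
power (exponent 0.8): the outer zones of such surveys are covered by
transects, so detection effort does not scale with area. A species' recorded
first-appearance distance is drawn area-uniformly inside its innermost
occupied band.

Pollen expected proportions integrate realised vegetation over distance with
an exponential kernel: the contribution of band b is the closed-form kernel
mass ∫ 2πr e^(−r/λ) dr over the annulus (annulus-area weighting), times the
species' abundance and habitat weight, summed into pollen types (consecutive
species blocks within each region/habitat segment, mean block size 2.5) and
multiplied by a per-type true productivity (log-normal, σ = 0.6, tree types
boosted 3×). The 25 highest producers are exposed as the analyst's PPE
table. A long-distance background (the regional mean composition, fraction
ε = 0.02) is mixed in; forest sites receive ε(1 + canopy_interception) to
represent canopy interception and washout of extra-regional rain. Counts are
multinomial with 2000 grains.

The effective source radius R_eff — the radius containing 85% of the
kernel-weighted pollen load inside the 1000 m survey limit — is closed-form
in λ and invertible (`lambda_for_source_radius`), and is recorded in the
ground truth. The `strong-signal` preset (40 open sites in one region,
one-to-one species/type map, uniform productivity, ε = 0.02, λ chosen so
R_eff = 150 m) is tuned for source-area recovery: patchiness there acts on
occupancy only, because abundance-evenness heterogeneity otherwise adds
pollen-richness noise that carries no spatial information.

**What the generator does not emulate:** real taxonomies (names are
synthetic), mechanistic atmospheric dispersal, geographic structure beyond
concentric bands, observer error in the plant survey, or inter-annual
variability of pollen deposition. Passing tests therefore show that the
pipeline recovers planted signals under a plausible generative model — not
that any particular field dataset satisfies that model.

## Numerical and design choices

- Seeding: one master seed; per-site streams are spawned from
  `SeedSequence`, so results never depend on processing order and runs are
  bit-reproducible.
- Shallow samples (total < depth) are excluded from rarefaction with a
  warning listing the sites; an all-shallow dataset is an error.
- Degenerate scans: zero predictor variance at a radius gives an undefined
  (NaN) adjusted R² excluded from the argmax; all radii undefined is an
  error.
- The dataset partition (two regions × {complete, forest, open}) is
  order-invariant (sorted site-id lists) and validated: subsets disjoint,
  complete = forest ∪ open.
- Plant and pollen taxonomies are treated as independent name spaces; the
  package never auto-harmonises species names to pollen types.
- Tolerances in tests: the Gower-vs-brute-force identity is enforced to
  1e-10; Monte-Carlo checks use 3-standard-error bounds; stochastic
  recovery properties use replicate rates (≥ 80% of 50 seeds for source-area
  recovery, ≥ 90% of 20 seeds for the richness rank order) at problem sizes
  (40–60 sites, 2000 grains, 100 rarefaction repetitions) chosen to keep a
  full run fast on one CPU.

## Known limitations

- The multinomial resampling law for productivity-adjusted counts is a
  modelling choice, not a mathematical consequence of the adjustment; the
  alternative rounding mode exists precisely because the choice matters at
  shallow depths.
- BD_Total comparisons between tables of very different richness are
  sensitive to the sqrt-transform convention; both modes are exposed.
- The significance marks along the radius grid are not corrected for the
  multiplicity of radii and should be read as descriptive.
- LCBD permutation p-values assume exchangeability within taxa across sites,
  which ignores spatial autocorrelation between nearby sites.
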