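# Methods

## The partitioning framework

All diversity quantities derive from a *metacommunity* (MC): a species x
subcommunity matrix of relative abundances `p` with grand sum 1.  From it we
form subcommunity weights `w_j = Σ_s p_sj`, within-subcommunity distributions
`p̂_sj = p_sj / w_j`, and pooled species frequencies `P_s = Σ_j p_sj`.  With
`M_r(w, x)` the weighted power mean of order `r` (geometric at `r = 0`), the
measures at viewpoint parameter `q ≥ 0` are

- normalized alpha  `ᾱ_j = [Σ_s p̂_sj^q]^(1/(1−q))` — the order-q Hill number
  of subcommunity j in isolation;
- representativeness  `ρ̄_j = M_{1−q}(p̂_·j, P_s / p̂_sj)` — 1 iff the
  subcommunity's composition equals the pooled composition, bounded below by
  `w_j` (a subcommunity always represents at least itself);
- subcommunity gamma  `γ_j = M_{1−q}(p̂_·j, 1 / P_s)` — the per-individual
  contribution of j to MC diversity, with the exact aggregation identity
  `M_{1−q}(w, γ_j) = γ` (the Hill number of `P`), which the test suite checks
  to 1e-10 relative on random matrices.

`q` tunes how much dominance matters: q=0 counts species, q=1 weighs them by
information (Shannon exponential), q=2 emphasizes dominants (inverse-Simpson
related).  Species similarity is the identity (naive) matrix throughout: the
similarity-sensitive generalization is out of scope.

Numerical choices: species with `p̂ = 0` carry zero weight and are excluded
from their subcommunity's species-weighted means, which keeps q=0 quantities
finite and equal to richness forms.  The q=1 branch is computed by dedicated
log-space formulas (never by evaluating near q=1); all power means run in log
space, so extreme abundance ratios cannot overflow.  `power_mean` routes
orders within 1e-9 of zero to the geometric branch and returns 0 when a zero
value carries positive weight at non-positive order.

### Averaging convention

Subcommunity values are averaged with the power mean of order `1 − q`
(arithmetic at q=0, geometric at q=1, harmonic at q=2) — the unique scale on
which subcommunity gammas aggregate exactly to the metacommunity gamma.  A
`convention="paper_literal"` switch instead maps q=1 to the harmonic and q=2
to the geometric mean, a mapping that appears verbatim in some descriptions
of this workflow; it is preserved for comparability but is not the default
because it breaks the aggregation identity.

## Partitioning designs

Four MC/SC designs answer the spatial and temporal questions: per-census
zone-level and ecosystem-level MCs with plots as SCs, and per-plot or
per-zone temporal MCs with censuses as SCs.  Because the network is
unbalanced (50/30/30 plots across zones), zone and ecosystem designs draw 30
plots per zone (without replacement, independently across 100 iterations,
seeded); zones at or below the target are used whole, and when no zone needs
subsampling a single realization is generated since no randomness remains.

Point estimates are order-(1−q) means over SCs within an iteration, then
arithmetic means over iterations.  The published workflow does not state a
CI method; we use a seeded percentile bootstrap (B = 1000) over the pooled
iteration x subcommunity values, which spans both subcommunity and
subsampling variability.  A single-subcommunity group yields a zero-width
interval and a `degenerate` flag.  Temporal designs require every census
year for every unit; nothing is imputed.

The package also reports the *zone-mean representativeness series*: the
zone-level spatial ρ̄ averaged over plots, per census.  A monotone rise in
this series is the operational signature of biotic homogenization (plots
converging in composition).  Per-year temporal ρ̄ is deliberately not used
for trend detection: under directional compositional change the pooled
four-census MC lies closest to the middle censuses, so that series is
hump-shaped by construction.

## Change indices

For a zone with species contributions `a_s` (start) and `b_s` (end) in
percent, the composition change is `%CC_s = 100 (b_s − a_s)/(b_s + a_s)`:
−100 for local extinction, +100 for introduction, invariant to uniform
rescaling of either census.  Species absent at both times are flagged
undefined and excluded (reporting 0 would fabricate stability).  The
range-change index is `(n_end − n_start) / |occupied_start ∪ occupied_end|`;
the union denominator is the only reading of "total plots at which the
species was present at both times" that is consistent with the stated ±1
endpoints besides the sum (available as `denominator="sum"`), and is the
more natural one.  Rounding happens only at presentation; every comparison
is made on unrounded values.

### The embedded abundance table

The packaged fixture carries the published zone-level counts for 1986 and
2014 (25 species, three zones; dash cells are explicit zeros).  Three
printed cells are internally inconsistent with the table's own counts; the
fixture and tests resolve them from the arithmetic: the hyposaline 2014
column's counts must sum to the printed total 18533 (every %CC cell
reproduces from that total and not from the raw column sum of 18534, so one
large count carries a +1 typo; the generalist's count is shipped as 8634),
the climax species' 1986 hyposaline contribution computes to 41.83 (its
printed %CC only reproduces from 41.83, so the printed 41.43 is a digit
typo), and one rare species' %CC computes to +4.74 against a printed +4.75.

## Kriging

Per-plot diversity values (computed against the MC pooling all plots at all
censuses, for maximal coverage) are interpolated by ordinary kriging onto
square grid cells of 625 m² (25 m cells) covering the padded bounding box of
the plot coordinates.  The empirical semivariogram is the Matheron
method-of-moments estimator on 12 equal-width lag bins to half the maximum
pairwise distance (all configurable).  Spherical, exponential and Gaussian
models — `c0 + c(1 − exp(−h/a))` and `c0 + c(1 − exp(−(h/a)²))` for the
latter two, with effective ranges 3a and √3·a recorded in output metadata —
are fitted by box-constrained least squares from a deterministic multi-start
grid; the family with the least (unweighted) SSE wins, ties breaking
spherical → exponential → gaussian.  Fits whose structured fraction
`c/(c0+c)` falls below 5%, or whose range collapses below the first resolved
lag, are flagged nugget-dominated.

Predictions solve the semivariogram-form system with a Lagrange multiplier
(weights sum to 1; exact interpolation at data points when the nugget is 0).
Duplicate coordinates are averaged, with a warning, before solving.
Leave-one-out cross-validation holds the fitted model fixed (no per-fold
refitting) and reports NRMSE = RMSE / (max z − min z); a constant field
yields NRMSE 0.  Between-epoch change is the fraction of grid cells moving
in a direction by more than a configurable ε (default 0; no claim is made
about any particular "distinct-area" threshold).  Coordinates are planar
meters; there is no geodetic handling, masking, or covariate-based
prediction.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
mangrove demography: 110 plots of 0.2 ha in three contiguous blocks
(50/30/30) along a salinity gradient (default 0.8–6 dS/m over a 10 km x 4 km
extent), with spatially correlated salinity noise (exponential covariance,
500 m–2 km scale, drawn by covariance factorization) so that kriged surfaces
have real structure (Moran-type autocorrelation > 0 is a tested property).
Expected counts follow Gaussian niches, `λ = A exp(r t) exp(−(s−μ)²/2σ²)`
with census index `t` = 0..3; counts are Poisson (a fixed-total multinomial
mode exists).  Base abundances are scaled so hyposaline plot totals are
~400 trees, the order of magnitude of the real network.  Species names
follow the published table for readable reports and carry no biological
claim.

`homogenization_scenario(strength)` maps a single knob onto the classic
homogenization recipe at full strength: fresh-end specialists decline
(−0.8/census log-abundance), facultative halophytes decline (−0.4), the
generalist expands (+0.45), the invasive obligate halophyte expands (+0.55),
and salinity rises 0.25 dS/m per census.  Generalist takeover is the
homogenizing engine: salinization alone *increases* hyposaline heterogeneity
because plots cross the climax species' niche edge at different times.
Strength 0 is exactly stationary.

What passing tests on this substrate do and do not show: they demonstrate
that the pipeline detects a known, planted homogenization signal of
realistic magnitude under Poisson sampling noise; they cannot validate the
niche parameterization against real mangrove data, nor the behavior under
observation error, taxonomic drift, or plot loss, none of which the
generator emulates.

## Problem sizes

Default analyses run the full 110-plot network with 100 subsampling
iterations and B = 1000 bootstrap replicates.  The test suite and worked
examples use the same network with fewer iterations and coarser grids
(100–400 m cells) — choices of scale only; every algorithmic path is
identical.

## Known limitations

- Representativeness CIs mix subcommunity and iteration variability; the
  published workflow does not say which was intended, and neither is
  privileged here.
- Beta/gamma surfaces inherit the high LOO-NRMSE typical of direct
  interpolation of composite indices; the alpha surfaces are the reliable
  ones (the cross-validation reports make this visible per run).
- The ANOVA/post-hoc layer of the original workflow is intentionally not
  reproduced; the tidy result tables are the hand-off point.
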