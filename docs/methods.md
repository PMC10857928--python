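# Methods

This note documents the models and procedures implemented in `montinv`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The scientific setting

Alien plant species in large mountain systems tend to be introduced at low
elevations (settlements, agriculture, transport corridors) and expand
upslope only slowly. This *directional filtering* predicts that
high-elevation alien assemblages are nested subsets of low-elevation ones,
and that the nesting is stronger for aliens than for natives, whose ranges
reflect millions of years of speciation, extinction and dispersal rather
than a recent, spatially biased colonisation front. The package provides
the full analysis chain used to test this prediction on elevational range
data: band-wise richness, phylogenetic clustering indices, nestedness
metrics with size/connectance corrections, a resampling test comparing the
two species pools, and regressions against climate and disturbance.

## Data model

A species record carries: status (native/alien), alien class (cultivated
takes priority over naturalised when both apply), an invasive flag,
source continents, biogeographic affinity (tropical/temperate/cosmopolitan),
occupied regions among the six west-to-east Himalayan divisions
(JK, HP, UK, NP, BR, AP), and an elevational range in metres. Records
lacking an elevational range are kept for pool tallies but excluded from
all band-based analyses; the reader reports how many were excluded and
flags invalid rows (e.g. inverted ranges) with their line numbers instead
of failing the whole file.

**Elevational bands** are half-open 200 m intervals `[L, U)` from 0 to
5000 m. A species occupies every band its range overlaps: `elev_min < U`
and `elev_max >= L`, with the top band closed above. The half-open rule
prevents double counting at shared boundaries; its one visible consequence
is that a range ending exactly on a boundary still reaches the band above
it (a point range [200, 200] occupies only [200, 400)).

## Band richness, grid assignment, IDW

Band richness is computed per group (all/native/alien/naturalised/
cultivated/invasive/tropical/temperate) by range interpolation, with the
alien proportion alien/(alien+native) per band. Band-wise group
correlations are plain Pearson r; zero-total bands are kept by default
(flag to drop), since dropping them is a data-dependent choice the caller
should make explicitly.

Grid assignment places a species in a 0.2° cell iff the cell's region is
among the species' regions *and* its range contains the cell's mean
elevation (closed interval). The inverse-distance-weighted surface uses
all known points with weights d^-p (p = 2 by default, Euclidean degrees;
great-circle km optional); a target coinciding with a known point returns
that value exactly, and every prediction is a convex combination of knowns.

## Phylogeny handling

Trees are rooted, branch-length-bearing Newick, wrapped around dendropy.
Tip binomials may be space- or underscore-separated; lookups accept both.

**Grafting** follows the basal-node approach used to place unsequenced
species on genus/family backbones:

* genus with ≥ 2 tips in the (growing) tree → new tip at the genus crown
  node (MRCA of its tips);
* genus with exactly 1 tip → a genus node is created half-way along the
  path from the family crown node to that tip (splitting whichever edge
  the midpoint falls on), and the new tip attached there;
* genus absent → new tip at the family crown node;
* degenerate one-tip families mirror the half-distance rule on the tip's
  stem edge.

The new tip's pendant length equals the mean root-to-tip depth of its
sister clade minus the attachment depth, so ultrametric backbones remain
exactly ultrametric and non-ultrametric ones get a sensible
"contemporaneous on average" placement. Grafts are applied sequentially,
so earlier grafts count as genus members for later ones. Patristic
distances among pre-existing tips are unchanged (edge splitting preserves
path lengths).

**MPD / MNTD** are the mean pairwise and mean nearest-taxon patristic
distances of a band's community. **NRI / NTI** are their negated
standardised effect sizes against a null of uniformly drawn, equal-sized
tip subsets of the group's own species pool, with 999 iterations by
default (seedable; the Monte-Carlo null converges to the exact uniform
moments). Positive values mean clustering; |index| > 1.96 is nominally
significant. Because the observed community under a random-assembly
simulation is itself a draw from the null, the index calibrates to mean 0,
SD 1 — verified over 500 random communities in the test suite. The index
is invariant to uniform branch-length scaling.

**Species:genus ratios** per band are rarefied for natives down to the
alien genus count (100 draws without replacement by default), reporting
the mean and the 2.5/97.5 percentiles.

## Nestedness

**NODF**: for each ordered pair of rows with strictly decreasing marginal
fills, the paired term is 100 × (shared presences)/(poorer row's fill);
equal fills contribute 0; likewise over columns. The total divides the sum
of paired terms by r(r−1)/2 + c(c−1)/2. Matrices are species × sites
(bands low→high or regions west→east); the column component carries the
directional claim and is reported separately. Empty bands are dropped
before computation, so occupied-band counts are emergent.

**Maximum NODF** at fixed dimensions and fill is found exactly by
exhaustive enumeration when the matrix has ≤ 16 cells. Above that, the
package first locates the best *staircase* (fully nested, left-justified)
matrix: for such matrices NODF depends only on the multiset of row fills,
and minimising the number of equal-fill pairs under the two linear
constraints (row count, total fill) has a near-linear-in-level continuous
optimum, which is rounded and polished by a deterministic local search
over fill-conserving profile moves. A seeded greedy hill-climb over
single-cell moves (2 restarts × 300 proposals by default) then explores
non-staircase improvements, which matter mainly at extreme fills and when
one dimension is small. The default budget recovers the exhaustive
optimum on every ≤ 16-cell case in the test suite; for the large matrices
used in the resampling comparison the staircase bound alone is within
about 2 % of the refined value and is used there (cached per shape/fill)
for speed. It is a heuristic bound by design: a slight underestimate of
the true maximum inflates NODFc equally for the two pools being compared
and cancels in their difference.

**NODFc** = (NODF / NODFmax) / (C · ln S), with connectance C = fill/(r·c)
and size term S = sqrt(r·c). The constant is isolated in one place and the
raw components (NODF, NODFmax, C, S) are always reported, so alternative
standardisation conventions (log10, other size terms) are recoverable from
the same result object. A completely filled matrix has NODFmax = 0; the
elevational wrapper then reports the raw NODF (0) and leaves NODFc
undefined rather than raising.

**treeNODF** replaces species counts by spanned branch length: a site's
branch set is every edge with at least one of its species below it, and
for site pairs with strictly decreasing total branch length the paired
term is 100 × shared length / poorer site's length. It decomposes exactly
into an S-fraction (edges carrying a species present in both sites) and a
T-fraction (edges shared only through internal topology). Terms are
averaged over **all** site pairs, the same denominator convention as
species NODF; this makes the star-tree case (equal pendant branches, no
internal structure) reduce exactly to the species-level column NODF with
zero T-fraction, which the test suite checks.

**Pool-resampling comparison.** For each occupied band, the observed
sample size is the number of range-bearing species (either status) present
in it, capped at the smaller pool with a warning. The configured number of
draws (100 by default) is taken without replacement from the native pool
and from the alien pool; each draw's species keep their full elevational
ranges, the incidence matrix is rebuilt and its NODFc computed. The
band-level difference is mean(alien) − mean(native); |Δ| > 0.05 is treated
as decisive, both per band and for the across-band mean. One NODFc is
computed per draw from the full rebuilt matrix (not per-band cells) — the
only reading under which a per-draw NODFc is well defined. Under
exchangeable pools the across-band flag fires in well under 10 % of
replicates at 25 draws per band, which the suite verifies.

## Driver regressions

Analysis units are 200 m belts below 4000 m (the 4000–5000 m belts carry
almost no aliens) or grid cells. Models are OLS with normal errors;
predictors are z-standardised before interaction fits so coefficients are
comparable; p-values are two-sided with no multiple-testing correction.
Rank-deficient designs raise with the aliased terms named. Collinearity is
screened by VIFs from auxiliary regressions (∞ reported for perfect
collinearity); because the simulated BIO6 is a noisy linear function of
elevation, including both inflates VIFs past 100 — the mechanism by which
elevation absorbs the climate signal in joint models. The alien-proportion
model is linear (not logistic) on native richness, slope per native
species. A seeded subsample-and-refit utility supports robustness checks
at reduced grid counts.

## The synthetic generator

The generator exists so every analysis runs end to end without downloads;
its defaults are the study conditions used throughout the tests.

* **Aliens** (n = 300): lower limit at the domain floor with probability
  0.9 (point mass at the introduction elevation), else uniform; upper
  limit = lower + Exponential(mean 800 m), truncated at 5000 m. The
  exponential was chosen because it is memoryless: one parameter tunes
  nestedness strength.
* **Natives** (n = 600): uniform midpoints with Exponential(1400 m) total
  extents (or a spreading-dye variant), i.e. no anchoring.
* **Affinity**: P(tropical) declines logistically in the range midpoint
  around 2000 m (scale 400 m), reproducing declining-tropical /
  mid-peaking-temperate richness shapes; 15 % of the remainder are
  cosmopolitan.
* **Taxonomy**: species are partitioned over 120 genera and genera over 30
  families with Zipf-like weights (few large genera, many small), shared
  deterministically between the pool and the backbone so the exemplar tips
  are pool species.
* **Backbone**: pure-birth family tree over the deepest 60 % of the crown
  depth, pure-birth genus trees below, one exemplar per genus, normalised
  to crown height 100. Conditioning on a fixed crown age means the birth
  rate shapes topology and relative node depths only — root-to-tip depth
  is invariant to it by construction.
* **Landscape**: 0.2° cells; elevation from a smooth latitudinal ridge plus
  N(0, 150 m) noise; BIO6 = 12 °C − 6.5 °C/km × elevation + N(0, 0.8);
  BIO12 linear west (800 mm) to east (3000 mm); footprint declining with
  elevation with a western bonus; regions as six longitudinal slabs.
* **Optional couplings**: `coupling_exponent` > 0 draws un-anchored alien
  midpoints with probability ∝ native band richness^exponent ("richer is
  more invaded"); `missing_range_rate` withholds elevations to exercise
  the exclusion pathway. Both default to off.

All draws descend from a single integer seed through named substreams, so
identical configurations give bit-identical CSV output.

What the generator does **not** emulate: real Himalayan topography or
hypsometry, spatial autocorrelation of ranges within regions, taxonomic
error, survey effort gradients, or any fitted resemblance to the real
flora. Passing tests therefore demonstrate that the *methods* detect the
structures they claim to detect under a known generative model — not that
the real flora has those structures.

## Numerical choices and degenerate inputs

* Ultrametricity tolerance 1e-6 relative to branch units for checks; the
  grafting tests assert 1e-9 on simulated backbones.
* Newick round-trips use 12-significant-digit branch lengths (distance
  matrices agree to 1e-9); CSV round-trips are lossless (repr floats).
* NODF paired terms with a zero-fill poorer line contribute 0 (arises only
  in exhaustive enumeration, never on pruned matrices).
* NRI with community = pool returns exactly 0; a zero-SD null with a
  proper sub-community raises rather than returning ±∞.
* Null-model sampling is vectorised and chunked (200 iterations at a
  time) to bound memory at large community sizes.
* Problem sizes used by the shipped tests and acceptance script — 20
  replicate seeds, 25 resampling draws per band, 299–499 null iterations,
  200–500 calibration communities — were chosen to give comfortable
  statistical margins for every decision rule at desk scale.

## Known limitations

* max-NODF above 16 cells is a heuristic; its occasional underestimate
  inflates NODFc slightly, consistently across compared matrices.
* treeNODF is O(site-pairs × edges × tips) in its S/T decomposition;
  fine for dozens of sites, not intended for thousands.
* The resampling comparison treats bands independently; draws are not
  shared across bands, so band-level flags are correlated only through
  the pools themselves.
* Grafting can make genera non-monophyletic when the half-distance
  midpoint falls above another split — inherent to the basal-node rule,
  not a defect of this implementation.
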