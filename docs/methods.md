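# Methods

`nichekde` quantifies the habitat niches of two potentially competing
steppe birds — the little bustard (*Tetrax tetrax*, displaying males) and
the great bustard (*Otis tarda*, mixed-sex flocks) — from occurrence
points on farmland land-use maps, and asks whether the little bustard's
niche responds to the density of its putative competitor.  This note
documents the model, the numerical choices, the synthetic data the
package tests itself on, and what those tests do and do not show.

## From points to niches

For every study site and year:

1. **Used area.** The 100% minimum convex polygon (MCP) over all
   observations of both species delimits the area actually used; its
   area (km²) is the denominator for bird densities (little bustard:
   male observations per km²; great bustard: individuals per km²).
2. **Availability.** Uniform random points are drawn inside the MCP,
   one per observed individual, never fewer than 30.
3. **Composition.** Habitat proportions over seven classes (cereal,
   ploughed, legume, young fallow, natural vegetation, dry woody
   culture, other) are extracted in a 100 m buffer around every bird and
   random point.  Buffers are evaluated on a 10 m raster of the field
   map (a 100 m disc covers ~314 cells; discretization error is a few
   percent at a boundary and much less on average; a polygon-exact mode
   exists for validation).  Buffers leaving the mapped extent are
   renormalized over the mapped part; buffers crossing the MCP edge
   into mapped land are deliberately not clipped.
4. **Ordination.** A single PCA, fitted on the pooled composition rows
   of all sites, years and origins, turns the 7 proportions into niche
   axes.  It is a covariance PCA on raw proportions (the variables are
   commensurate; correlation mode is a config switch).  Three axes are
   retained by explicit choice, and each axis is sign-oriented so that
   an anchor habitat loads positively (PC1→cereal, PC2→ploughed,
   PC3→natural vegetation), making refits reproducible.  No log-ratio
   transform is applied to the compositional data; with a 7-part
   composition dominated by a few classes this is standard practice in
   this literature but remains a known limitation.
5. **Kernel niches.** For each axis pair (PC1–PC2, PC1–PC3, PC2–PC3)
   and each site-year, a weighted bivariate Gaussian KDE is estimated
   from the bird scores (weights = individuals per observation) and,
   separately, an *environmental niche* from the random points (weight
   1).  All densities of one axis pair are evaluated on one shared
   grid — 151×151 cells spanning the pooled score range padded by 15%
   per side — so that breadth, position and overlap are comparable
   across site-years.  A KDE is only estimated when at least 10
   individuals (five per dimension) and at least 10 observation points
   are available; failures are logged per site-year, and a config list
   allows manual exclusions (the per-KDE diagnostics — number of
   HDR fragments, boundary mass fraction, captured mass — support that
   review, but no exclusion is automated).

### Plug-in bandwidth

Bandwidth matrices are unconstrained 2×2 SPD plug-in selectors: the data
are sphered with the Cholesky factor of the weighted covariance, the
five order-4 integrated density-derivative functionals ψ_r are estimated
with a Gaussian pilot at the normal-scale rate g = (2/(6·n_eff))^(1/8),
and the asymptotic MISE surrogate

    PI(H) = (4π)^{-1} |H|^{-1/2} / n_eff  +  ¼ · vech(H)ᵀ Ψ₄ vech(H)

is minimised over SPD matrices through a log-Cholesky parametrisation
(Nelder–Mead).  Weights enter through the weighted moments and the
effective sample size n_eff = (Σw)²/Σw², so uniformly scaling all
weights changes nothing; sphering makes the selector exactly
equivariant under linear maps of the data.  If the optimisation fails
or runs to its box bounds the selector falls back, with a warning, to
the d=2 normal-scale matrix H = n_eff^{-1/3} Σ̂.  For Gaussian data the
criterion's exact minimum is n^{-1/3} Σ, which the tests bracket.

Kernel tails are truncated at 8.6 standard deviations (relative error
below double precision), which lets the evaluator use per-point windows
on the grid; the evaluation is numerically exact.

### Niche statistics

All three statistics use the 95% highest-density region (HDR): grid
cells sorted by density, accumulated until 95% of the probability mass,
boundary cell included.

* **Breadth** — number of grid cells in the HDR (grid-dependent, hence
  only comparable on the shared grid).
* **Position** — cell-centre coordinates of the density maximum; ties
  break to the lowest linearised cell index.
* **Overlap** — ∫ min(f_a, f_b) over the whole shared grid, clipped to
  [0, 1].  The default integrates the untruncated densities so that
  identical niches score exactly 1; an `hdr_union` mode restricting the
  integral to the union of the two 95% regions is available, since some
  practitioners compute overlap on the truncated niches instead.

Grid integration satisfies Σ f·cellarea ∈ [0.98, 1]; a captured mass
below 0.9 raises an error advising a larger padding.

## Mixed models

Three Gaussian linear mixed-model designs, all with a random intercept
per study site:

1. overlap ~ great-bustard density (sympatric, overlap-eligible
   site-years);
2. breadth / position(dim1) / position(dim2) ~ great-bustard presence +
   the matching environmental-niche covariate (all site-years) — the
   ecological-release contrast; the environmental covariate controls
   for the functional response of habitat use to availability;
3. the same responses ~ little-bustard density + great-bustard density +
   environmental covariate (sympatric site-years only) — the
   density-dependent test.

Estimates, standard errors and Wald t statistics come from REML fits
(statsmodels `MixedLM`); per-term likelihood-ratio χ² values come from
ML refits with and without the term.  Wald p-values refer t = β̂/SE to a
t distribution with n − k − 1 residual degrees of freedom rather than
the normal approximation, which is anticonservative at n = 16–26; no
multiple-testing correction is applied across the 9–18 models
(the field protocol applies none; documented, not endorsed).  A zero random-intercept variance is a boundary fit and is
flagged, not an error; exactly degenerate designs (zero residual
variance, e.g. a response equal to a covariate) fall back to least
squares with a `degenerate` flag.

## Synthetic study generator

The package ships no real field data, so it includes
a generator that reproduces the *statistical structure* the analysis
assumes, and every claim the tests make is a claim about data of this
structure:

* **Landscape** — a grid of square fields (default edge 150 m, a
  typical ~2 ha dryland parcel; buffers then span only a few fields, so
  compositions are informative rather than uniform mixtures) labelled
  i.i.d. from a habitat mix.  In the default study design the mix
  varies per site-year: cereal U(0.26, 0.40); the unsown rotational
  land is split U(0.25, 0.75) between ploughed fields and young fallow
  (they are alternative states of the same substrate, which is what
  creates the ploughed-vs-fallow ordination axis); legumes are present
  in ~60% of site-years at 5%; natural vegetation (10%), dry woody (5%)
  and other (5%) are stable.  Cereal + ploughed average ≈ 50% of the
  surface.
* **Birds** — observation locations are drawn with probability
  proportional to the preference weight of the habitat under each
  candidate point, with a Thomas cluster process (Gaussian scatter
  around Poisson parents) for spatial aggregation.  Little bustards:
  one male per observation, weights (cereal 1.0, ploughed 0.1, legume
  1.5, young fallow 2.0, natural vegetation 2.0, woody 0.2, other
  0.05), cluster scale 400 m (exploded-lek structure).  Great
  bustards: shifted-Poisson flocks of mean 4 birds, near-uniform
  preferences, cluster scale 250 m (conspecific attraction).
* **Displacement (the competition switch)** — a little-bustard
  candidate location in cereal is displaced with probability
  1 − exp(−γ·D), where D is the great-bustard density (individuals/km²)
  within 500 m, and the displaced bird resettles in a uniformly chosen
  natural-vegetation field.  The resettlement is directional on
  purpose: redistributing displaced birds pro rata over the remaining
  habitats splits them evenly between young fallow and natural
  vegetation, whose PC3 loadings have opposite signs, and therefore
  cancels the niche-position shift that displacement toward the primary
  habitat should produce.  γ defaults to 0.5, calibrated so that a
  typical 4-bird flock (5.1 birds/km² within 500 m) suppresses local
  cereal use by ~92% — i.e. little bustards essentially cease to use
  cereal inside the interaction radius of foraging great bustards.
  Both the exponential kernel and the 500 m radius are synthetic
  stand-ins: no quantitative interaction kernel is published for these
  species, only the qualitative displacement out of cereals toward the
  primary habitat.
* **Default design** — 9 sites, 26 site-years; three sites never hold
  great bustards and one further site-year has none, so 16 site-years
  are sympatric and 10 allopatric; per-site-year observation counts
  (little bustard 12–134 observations, great bustard 0–140 individuals)
  follow the magnitudes typical of such multi-site censuses, and exactly 9
  sympatric site-years clear the 10-individual gate for both species
  and hence enter the overlap analysis.  All randomness derives from
  one master seed through stable per-site-year hashes; studies are
  byte-reproducible.

**What the generator does not emulate:** detectability and census
error, within-season movement and lek dynamics, female little bustards,
real parcel geometry (fields are square and i.i.d.; no spatial
autocorrelation of crops), and any behavioural response of great
bustards to little bustards.  Passing recovery tests therefore show
that *if* displacement of this form is present at this strength in data
of this shape, the KDE-plus-LMM chain detects it with the right sign —
not that the published effect sizes are reproduced, which would require
the undeposited field data.

## Problem sizes used in validation

The acceptance suite runs the analytic overlap oracle at n = 20 000
points per species on a 301² grid; the HDR oracle at 401² (direct) and
n = 5 000 with plug-in bandwidth; and the recovery experiment on the
full default design with a 48×48 evaluation grid and the two axis pairs
the hypotheses concern — sign and significance of the mixed-model
coefficients are invariant to the grid scale, which only sets the
resolution of the breadth/position statistics.  Single default-study
runs (CLI, acceptance script) use the full 151×151 grid and all three
axis pairs.

## Known limitations

* Compositional data enter the PCA untransformed; axes can mix closure
  effects with ecological gradients.
* The KDE mode (niche position) is an intrinsically noisy statistic on
  flat-topped densities; single-study position estimates carry cell-size
  jitter, which is why recovery claims are about signs across replicate
  studies.
* Breadth depends on the bandwidth and hence on sample size
  (n_eff^{-1/3} smoothing inflates small-sample niches); comparisons
  across site-years inherit that bias exactly as the field protocol
  does.
* The plug-in selector uses one pilot stage with a normal-scale rate,
  not a full multi-stage SAMSE pilot; for the sample sizes involved the
  difference is well inside the acceptance bracket against the
  normal-scale matrix.
* `MixedLM` Wald p-values are asymptotic; at n = 16 they are mildly
  anticonservative, which the type-I acceptance band accounts for.
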