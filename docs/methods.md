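# Methods

## Problem and model

The package classifies a 1-D transect twice — once from dense environmental
data (SST, SSS) and once from sparse community data (stations × OTU relative
abundances) — using the same prototype-based fuzzy c-means, and then treats
the *membership profiles* u(x) as the observable from which spatial structure
is read. Because memberships are continuous in (0, 1), the boundaries between
clusters appear as smooth ramps rather than hard cuts, and their geometry
(location, maximum slope, curvature extent) quantifies the ecotone.

FCM is fitted with explicit centroids (Bezdek form) rather than a
medoid/dissimilarity objective because downstream analyses need the centroid
*composition*: water-mass T/S signatures and per-OTU centroid abundances.
Memberships follow u_ik = 1/Σ_j (d_ik/d_ij)^{2/(m−1)}; an observation
coincident with one or more centroids gets its unit membership split equally
among the coincident centroids. Each fit is the best of `n_starts` (default
20) runs from flat-Dirichlet initial memberships; the objective is recorded
per iteration and is non-increasing. The cluster-count bound k ≤ ⌊n/2⌋ − 1 is
enforced by default (8 stations ⇒ k ≤ 3) and `select_k` maximizes the
normalized partition coefficient, breaking ties toward the smaller k.

Preprocessing: SST/SSS are z-scored per month; community matrices get the
Hellinger transform (square root of row proportions), which makes Euclidean
FCM a defensible community dissimilarity. Both transforms record their
parameters so centroids can be inverted to °C/PSU or % units (the Hellinger
inverse squares and renormalizes, since FCM centroids do not lie exactly on
the unit sphere).

## Ecotone metrics

Membership profiles are smoothed with a cubic smoothing spline. For dense
profiles the penalty is chosen by scipy's generalized cross-validation; for
short profiles (< 30 points, i.e. the 8 community stations) an explicit GCV
search over a log-spaced penalty grid is used with the hat-matrix equivalent
degrees of freedom capped at n − 2, which prevents near-interpolation
artifacts in the derivatives. Derivatives are evaluated analytically from
the spline on a grid of step ≤ 0.1 km (default 0.05), never beyond the data
range.

Transitions are prominent local extrema of f′. Prominence is measured in
membership units as the integral of the (sign-corrected) derivative over its
lobe — i.e. the membership swing the edge mediates — with a default floor of
0.05, which suppresses noise micro-extrema without touching real edges.
Transition width is the distance between the two flanking f″ extrema of the
correct curvature sign (for a falling edge the signs flip; handled by
sign-aware search). For a logistic edge of scale s the closed forms are
slope = 1/(4s) and width = 2s·ln((3+√3)/(3−√3)) ≈ 2.634 s; the tests hold
the implementation to 1% and 2% of these.

A boundary between two spatially adjacent clusters A and B is estimated by
pairing a falling edge of A with a rising edge of B within 8 km, preferring
the pair whose weaker member has the largest prominence (gap-only matching
occasionally pairs two noise wiggles); the boundary location/slope/width are
the means of the paired records.

Two caveats are inherent to membership-derivative geometry. First, the
steepness of a membership ramp conflates the environmental gradient width
with the *separation of the adjacent centroids in feature space*: two water
masses close in T/S (e.g. a front and the sub-Antarctic water behind it)
flip memberships over a shorter distance than the mixing scale alone
implies, so membership transition widths can compress relative to the
physical mixing widths even when the slope ranking is preserved. Second, at
a diffuse low-contrast boundary the location estimate (argmax |f′|) is
noise-sensitive: under the default noise it wanders with an SD near 1 km,
while its month-averaged value stays well within ±1 km of truth. Both
behaviours are quantified by `ecotransect.evaluate.evaluate_recovery`.

## Synthetic transects

The generator is the package's ground-truth instrument. Water-mass mixing
weights are products of logistic edge functions (rising at the mass's left
edge, falling at its right), renormalized to sum to 1 — exactly 0.5/0.5 at an
isolated boundary midpoint — so boundary locations and scales have closed
forms. Defaults (one choice, not revisited): four masses with T/S signatures
NW 13.15 °C/34.32 PSU, STW 12.32/34.67, FRONT 11.30/34.42, SAW 10.78/34.31;
boundary midpoints 14, 29.5 and 46.5 km on a 65-km transect (mean front patch
width 17 km), jittered ±5 km per month (uniform, seeded, minimum 2-km gaps);
logistic scales 1.4/1.2/2.4 km so the mid-transect boundary is twice as sharp
as the offshore one and the inshore one is a near-tie with it; measurement
noise 0.15 °C and 0.02 PSU; 8 stations evenly spaced at 1–64 km; months
Jan/Mar/Apr/Jun/Jul/Dec (no seasonal trend in boundary positions).

Communities: 600 OTUs = specialists (30/30/12/30 for NW/STW/FRONT/SAW — the
front is a mixing zone and carries fewer unique taxa, so its community can
merge with a bordering one while STW and SAW stay distinct), 60 ubiquitous,
and 420 rare OTUs, each rare OTU tied to a home month and appearing at 1–3
random stations (2% leak probability elsewhere). Specialist and ubiquitous
base abundances are log-normal (the paper-free choice; abundance
distributions of marine OTU tables are heavy-tailed). Expected station
composition is the mixing-weighted specialist pool plus the ubiquitous
baseline; sequencing is one multinomial draw at a uniform 15–30k library
size, rarefied 10× to depth 10,000, averaged, rounded half-to-even and
converted to % (rows sum to 100). With these settings ≈41–43% of the global
OTU pool is detected per month.

What the generator does **not** emulate: taxonomic correlation structure,
compositional overdispersion beyond multinomial, PCR/primer bias, chimeras,
within-month temporal variability, 2-D structure. Passing tests therefore
demonstrate method correctness under a known 1-D mixing model, not
performance on raw amplicon data.

## Shared-OTU network and spinglass

An OTU's membership grade in a community cluster is operationalized as its
share of centroid abundance across clusters (in (0,1), summing to 1), and a
cluster's representative pool is the OTUs whose top share ≥ τ; this is an
interpretation choice — several species-membership concepts exist — made for
reproducibility and because it behaves correctly at the 0.85 threshold
(exclusive OTUs always qualify, evenly spread ones never do). Raising τ
shrinks pools monotonically, hence never increases an edge weight.

Spinglass modules minimize H = −Σ_{i<j}(A_ij − γ k_i k_j/2m)δ(σᵢ,σⱼ) with
γ = 1 on weighted edges. The annealer uses Metropolis single-spin moves over
min(n, 25) states, a start temperature calibrated so ~80% of early proposals
accept, geometric cooling (factor 0.99/sweep, ≤1000 sweeps, early stop), and
a zero-temperature quench alternating single-spin descent with community
merges (a community split in two is a single-move trap that only a merge
repairs). Each reported run is the best of 8 such attempts; on ≤8-node
graphs this matches an exhaustive-search energy minimum in ≥99% of runs.
"Repeated over 1000 networks" is read as 1000 independent optimizer runs on
the same network; partition frequencies above 1% are reported. Isolated
components are listed separately rather than clustered.

## Group statistics

Kruskal–Wallis uses scipy's tie-corrected H with the χ² approximation even
at n = 6–12 per group (caveat: at such sizes the approximation is only
approximate; empirical type-I error at α = 0.05 stays ≤ 0.07 in the tests).
Dunn's z uses the pooled mid-ranks with the tie-corrected variance and
Bonferroni multiplication by the number of pairs. The compact letter display
is greedy insert-and-absorb (valid, not guaranteed minimal). Seasons map
months via the southern-hemisphere convention.

## Numerical choices and degenerate inputs

- FCM convergence: max-abs membership change < 1e-8, ≤500 iterations.
- Zero distances: singleton rule (above); zero-variance variables under
  z-scoring raise; community rows off 100% by >1% renormalize with a warning.
- 0·ln 0 := 0 in the partition entropy.
- Rounding of averaged rarefaction counts is half-to-even.
- Community clusters get a second water-mass label when a second mass's
  profile correlation is within 0.05 of the best; below correlation 0.3 the
  cluster is "unassigned".
- Problem sizes used by the validation suite: 50 transects for recovery
  scoring, 1000 spinglass runs for consensus, 10,000 null datasets for the
  type-I check — sizes chosen to make the rates stable at the asserted
  thresholds.

## Known limitations

- Membership-derivative widths compress at low-contrast boundaries (above);
  comparisons of widths across boundaries are reliable only when centroid
  separations are comparable.
- The fuzziness exponent m = 2 is conventional, not estimated; memberships
  (and hence ecotone widths) depend on it.
- No possibilistic/noise-cluster variant: outliers are absorbed into the
  nearest clusters.
- The χ² approximation at n = 6 is anticonservative in the extreme tails;
  no exact permutation option is provided in this version.
- The smoothing-spline family is itself a choice; a fixed-span local
  quadratic can be emulated by fixing the penalty (`lam=...`), and
  sensitivity of the transition table to the smoother should be checked on
  real data.
- With 8 stations ~9 km apart, community transition slopes and widths are
  resolution-limited by the station spacing, not by the underlying mixing
  scales (1–3 km): slope ratios between community boundaries are therefore
  near 1 and noisy, while the environmental ratios (from the dense track)
  are informative. The reporting script exposes both.
- The generator keeps each water mass's specialist pool fixed across months,
  so representative OTUs recur month after month and the fraction of
  representative OTUs shared between pools runs far higher than in real
  systems with month-to-month community turnover; within-mass network links
  remain correctly stronger than between-mass links.
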