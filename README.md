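# ecotransect

Fuzzy-clustering analysis of 1-D oceanographic transects: detect water masses
and microbial community patches as *overlapping* fuzzy clusters, measure the
ecotones (transition zones) between them from the derivatives of membership
profiles, and summarize how the communities of different months and water
masses relate through shared-OTU networks.

The package targets coastal-to-offshore surveys of the kind where a ship
records continuous sea-surface temperature (SST) and salinity (SSS) along a
~65 km track crossing several water masses — neritic waters (NW), subtropical
waters (STW), a subtropical front (FRONT) and sub-Antarctic waters (SAW) —
while 16S amplicon samples from a handful of stations yield an OTU relative
abundance matrix per month. It is equally usable for any 1-D gradient with a
dense environmental track and a sparse community matrix.

## The method

**Fuzzy c-means (FCM).** Observations x₁…xₙ (standardized SST/SSS, or
Hellinger-transformed OTU abundances) are partitioned into k fuzzy clusters
by minimizing

    J = Σᵢ Σₖ u_ik^m ‖xᵢ − v_k‖²,   Σₖ u_ik = 1,  u_ik ∈ (0,1)

with the alternating updates u_ik = 1 / Σⱼ (d_ik/d_ij)^{2/(m−1)} and
v_k = Σᵢ u_ik^m xᵢ / Σᵢ u_ik^m (fuzziness m = 2 by default). The number of
clusters cannot exceed ⌊n/2⌋ − 1, so 8 stations admit at most 3 community
clusters; k is chosen by the normalized partition coefficient
PC_norm = (PC − 1/k)/(1 − 1/k), PC = (1/n)ΣΣ u², with the normalized
partition entropy PE/ln k reported alongside.

**Ecotone geometry.** Each cluster's membership-vs-distance profile is
regressed on distance with a cubic smoothing spline (penalty chosen by
generalized cross-validation). A boundary is a prominent local extremum of
the first derivative: its position is the transition *location*, |f′|max is
the *abruptness* (slope, 1/km), the distance between the two flanking
extrema of f″ is the *transition width*, and spacing of consecutive |f′|
extrema gives the *patch widths*. For a logistic edge of scale s these equal
the midpoint, 1/(4s), and ≈2.634·s, which the tests verify.

**Centroids and representative OTUs.** Community-cluster centroids are
mapped back to natural % units; an OTU's membership grade in a cluster is
its share of centroid abundance across clusters, and OTUs whose top share
reaches τ (default 0.85, swept over 0.75–0.99) form the cluster's
representative pool. Clusters are tied to water masses by correlating their
membership profiles with the environmental ones at the stations.

**Shared-OTU network.** Nodes are (month, water mass) community clusters;
edge weights count shared representative OTUs. Modules are found by
minimizing the Reichardt–Bornholdt spinglass Hamiltonian
H = −Σ_{i<j} (A_ij − γ·k_i k_j/2m) δ(σᵢ,σⱼ) with simulated annealing,
repeated 1000 times; the modal partition and all partitions above 1%
frequency are reported.

**Group statistics.** Transition slopes and widths are compared across
boundary types, months and (southern-hemisphere) seasons with Kruskal–Wallis
tests, Dunn's post-hoc z tests and Bonferroni adjustment, summarized as a
compact letter display.

A synthetic-transect generator with known ground truth (logistic water-mass
mixing, specialist/ubiquitous/rare OTUs, multinomial sequencing with 10×
rarefaction averaging at depth 10,000) drives the test suite end to end.

## Worked example

```python
import numpy as np
from ecotransect import TransectScenario, generate_dataset
from ecotransect.evaluate import analyse_month

scenario = TransectScenario()                       # 4 masses, 8 stations, 6 months
env, communities, truth = generate_dataset(scenario, seed=42)
jan = env[env["month"] == "Jan"]
result = analyse_month(jan, communities["Jan"], scenario, np.random.default_rng(0))

for b in result.boundaries:
    print(f"{b['pair']:>10}: location {b['location_km']:5.1f} km, "
          f"slope {b['slope_per_km']:.3f} /km, width {b['transition_width_km']:.1f} km")
print("community clusters:", ["+".join(l) for l in result.community_labels])
print("true boundaries:   ", [round(d["midpoint_km"], 1) for d in truth.boundaries["Jan"]])
```

prints

```
    NW|STW: location  13.0 km, slope 0.338 /km, width 1.0 km
 STW|FRONT: location  32.5 km, slope 0.324 /km, width 2.6 km
 FRONT|SAW: location  49.0 km, slope 0.135 /km, width 2.9 km
community clusters: ['STW', 'SAW', 'NW']
true boundaries:    [12.7, 32.8, 49.6]
```

The three detected boundaries sit within a few hundred metres of the
generator's jittered truth; the mid-transect STW|FRONT boundary is more
than twice as steep as the diffuse FRONT|SAW boundary (its true logistic
scale is half as wide), and the three community clusters map onto STW, SAW
and NW — in this month the front's community is merged with a neighbour, as
happens when the front patch covers too few stations.

## Command line

Every stage is a subcommand over a YAML config (`ecotransect simulate`,
`cluster-env`, `cluster-otu`, `ecotones`, `centroids`, `network`, `stats`,
`run-all`); outputs are CSV/TSV/GraphML/JSON plus a manifest with checksums,
so identical config + seed reproduce identical numbers.

```bash
ecotransect run-all --outdir myrun --seed 7
```

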