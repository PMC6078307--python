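# Methods

This package implements a tripartite association analysis linking
three data blocks measured on the same cohort: fecal tryptophan
metabolites (indole, skatole, indoleacetic acid), clinical/behavioral
scores (BMI, Yale Food Addiction Scale, HAD anxiety), and graph-
theoretic centrality of extended-reward brain regions derived from
resting-state and diffusion imaging. It operates downstream of image
preprocessing: its inputs are region-level time series and fiber-count
matrices, which here are produced by the package's own synthetic
cohort generator.

## Connectome construction

**Functional.** For each subject, the pairwise Pearson correlation
r_ij of region time series is Fisher z-transformed, z = atanh(r), and
an edge is retained iff z > 0.3 (strictly; ties at the threshold are
removed). The retained z magnitude is the edge weight, so functional
weights are either 0 or > 0.3, and negative correlations never
survive a positive threshold. Thresholding in z is equivalent to
r > tanh(0.3) ≈ 0.2913. r is clipped to ±(1 − 1e−12) before atanh so
duplicated signals produce large finite weights rather than
infinities. Constant-signal regions cannot be correlated; their edges
are zeroed with a logged warning.

**Anatomical.** The edge weight is the fiber count between two
regions divided by the *sum* of their volumes. The source phrasing
("fiber count divided by the individual volumes of the two
interconnected regions") is ambiguous; the sum is the common
streamline-density convention and is the default, with `product` and
`mean` selectable via the `anat_norm` configuration key. Weights
scale as 1/c when all volumes are scaled by c.

Both matrices are symmetric, nonnegative, and zero-diagonal over the
same 165-region parcellation (74 cortical labels per hemisphere, 7
subcortical per hemisphere, cerebellum per hemisphere, brain stem).
Centrality is computed on the **whole** network; the 12 reporting
ROIs (nucleus accumbens, amygdala, and four anterior-insula
substructures, per hemisphere) only select which nodes are reported.

## Centrality

Two indices per ROI node and modality:

* **Degree strength** S_i = Σ_j w_ij, the weighted degree. The
  weighted definition is used (rather than a binary edge count)
  because that is the standard strength measure for weighted
  connectomes; a `binary_degree` option exists.
* **Betweenness centrality** B_i = Σ_{s<t, s≠i≠t} σ_st(i)/σ_st,
  unnormalized, endpoints excluded, all tied minimal paths credited
  fractionally. Edge distance is 1/weight by default (−log(weight)
  selectable, valid only for weights in (0, 1) — Fisher-z weights can
  exceed 1). The implementation is Brandes' dependency accumulation
  over Dijkstra shortest paths, with one deliberate deviation from
  common library implementations: two path lengths are considered
  tied when they agree within a relative tolerance of 1e−12, so
  floating-point rounding cannot split what is substantively a tied
  pair of routes. An exhaustive simple-path-enumeration oracle with
  the same contract (`brute_force_betweenness`, ≤ 9 nodes) exists
  purely for verification, and the test suite additionally
  cross-checks against networkx.

Variable labels follow the `S_/B_ + hemisphere + structure` scheme
(e.g. `B_R_NAcc` = betweenness of the right nucleus accumbens), with
modality carried separately (`func:`/`anat:` prefixes in wide tables
and network node ids).

## Association screen

Every cross-block pair is tested — 3 metabolites × 48 brain metrics,
3 clinical × 48 brain metrics, 3 × 3 metabolite × clinical = 297
tests; within-block pairs are never tested. Each test is a partial
Spearman correlation controlling for age and sex: variables and
covariates are average-rank transformed on the pairwise-complete
subjects, both ranked variables are residualized on an intercept plus
the ranked covariates by least squares, and r is the Pearson
correlation of the residuals. Two-sided p-values come from
t = r·sqrt(df/(1 − r²)) with df = n − 2 − k. Covariates are counted
at their effective rank (a constant covariate consumes no degrees of
freedom, making the screen reduce exactly to plain Spearman in that
case). Because published association tables in this area sometimes
print df = n − 1, both conventions are emitted (`df_test`,
`df_printed`).

Pairwise-complete (not listwise) case selection is used: YFAS pairs
use only the 42 completers, anatomical pairs lose the one excluded
diffusion scan (n = 62), reproducing the characteristic df variation.
Pairs with fewer than k + 4 complete cases or zero rank variance are
flagged and excluded from the FDR family rather than failing the run.

Benjamini–Hochberg q-values are attached within families. The default
family key is (block pair × brain modality) — five families — because
q non-monotone in p across a pooled table indicates sub-family
correction in the source material; `pooled` and `block_pair` are
selectable. Sex is coded numerically (0 = female, 1 = male).

## Tripartite network

Records passing the threshold become edges; nodes inherit their block.
Two thresholdings are first-class: the FDR-corrected network
(q < 0.05) and the visualization network (p < 0.05), each edge
carrying a `q<0.05` / `p<0.05` tier flag. The reported subnetwork
keeps the metabolites, their first neighbors, and *all adjacent
edges*: every edge with at least one endpoint in the
metabolite-plus-neighbor set is retained together with its outer
endpoint, so a clinical score linked only to a metabolite's brain
neighbor remains visible — this is precisely what certifies
brain-mediated indirect paths.

Each (metabolite, non-brain partner) pair is classified **direct**
when the pair shares an edge and **indirect** when it does not but at
least one brain-metric node is adjacent to both. The shared brain
neighbors (`mediators`) are reported for *every* pair, including
direct ones, because a directly associated pair can additionally
exhibit brain-mediated length-2 paths and the source results describe
both for the same pair. Mediators are restricted to brain-metric
nodes. Exports: GraphML and TSV (lossless round-trip), SIF (topology
plus sign of r as `pos`/`neg`).

## Synthetic cohorts

The generator reproduces the study's marginal conditions: 63 subjects
(29 male / 34 female), age ~ N(29.42, 10.76²) truncated to [18, 60],
BMI ~ N(25.82, 4.93²), YFAS ~ N(1.24, 1.25²) rounded and clipped to
[0, 7] with exactly 42 completers (missingness is assigned to the
*last* subject ids so pairwise-complete sample sizes are
reproducible), HAD anxiety ~ N(4.25, 3.41²) rounded and clipped to
[0, 21], and log-normal metabolites. Metabolite units and
distributions are not documented for the source assay, so log-normal
margins with log-means 4.0/2.0/3.0 and log-SDs 0.8/0.9/0.7
(indole/skatole/IAA, arbitrary units) are an assumption, flagged in
the configuration. One anatomical scan (the last subject) is excluded
by default, emulating a failed quality-control scan.

Cross-block dependence is induced by a single latent factor L per
subject: a variable with loading ρ_v is μ_v + σ_v(ρ_v L +
√(1−ρ_v²)ε) before its marginal transform, so a planted pair
(a, b, ρ) has latent-scale correlation ρ_a·ρ_b = ρ. The same L can
shift designated time-series correlations additively (β·L, clipped to
±0.99, with eigenvalue-clipping PSD repair at 1e−8 and diagonal
renormalization) and fiber intensities multiplicatively (exp(γ·L)).
For calibration experiments that need an *exact* metric-level planted
correlation, a brain-metric block can be generated directly on the
latent scale (`generate_metric_block`) — the imaging route cannot be
calibrated to a target metric correlation.

Time series are zero-mean multivariate normal draws (243 samples by
default: one ~8-minute scan at TR = 2 s) from a block correlation
structure: four round-robin communities with within/between
correlations 0.35/0.20 — values chosen to sit
near the retention threshold tanh(0.3) ≈ 0.29 so that thresholded
edge sets, and hence path structure, vary across subjects instead of
freezing into identical cliques. Fiber counts are Poisson-lognormal
(means 120 within / 25 between communities, dispersion 0.5) because
overdispersion is what makes anatomical shortest paths
subject-specific. These are the generator's defaults and are
configurable.

What the generator does **not** emulate: spatial autocorrelation and
hemodynamics of real BOLD signals, distance-dependent tractography
biases, scanner/site effects, realistic metabolite assay noise, or
any causal structure — a single shared latent factor is the simplest
mechanism producing the tripartite correlation pattern. Passing tests
therefore demonstrate correctness and calibration of the *analysis*,
not validity of any neurobiological claim on real data.

## Numerical choices and degenerate inputs

* Ranking uses average ranks for ties throughout.
* Betweenness distance ties: relative tolerance 1e−12.
* Functional r clipped at ±(1 − 1e−12) before atanh.
* PSD repair: eigenvalues clipped at 1e−8, diagonal renormalized.
* Zero-variance variables (after ranking on the complete cases)
  produce flagged, excluded records, never exceptions.
* t_points ≤ n_regions logs a rank-deficiency warning but proceeds.
* All randomness flows from one seed through named per-stage child
  generators, so every stage is independently reproducible and full
  runs are byte-identical.

## Problem sizes

The statistical experiments run on reduced connectomes (20 regions
containing all 12 ROIs) because the screening statistics — counts of
tests, calibration, recovery — do not depend on the number of filler
regions: the full-pipeline global-null experiment uses 500 cohorts of
n = 63, and planted-effect recovery uses 200 cohorts (100 in the
acceptance script, with 200 null cohorts there). The full 165-region
pipeline runs in well under a minute per cohort and is exercised
end-to-end by the CLI and the worked example.

## Known limitations

* The Benjamini–Hochberg bound on the probability of *any* false
  discovery under the global null assumes independent (or PRDS)
  tests. Centrality metrics of 12 ROIs in a 20-region graph share
  most of the network's edges and are strongly interdependent; our
  own null experiments measure an any-discovery rate slightly above
  the nominal 5% under this dependence (while the same screen on an
  independent synthetic metric block is consistent with 5%, and
  per-test p-values are well calibrated into the far tail). This is a
  property of BH under dependence, not of the implementation.
* The t approximation for rank correlations is the field convention
  but is not exact at small n; no exact permutation option is
  provided.
* The latent-factor generator produces jointly Gaussian dependence on
  the latent scale; planted Pearson correlations translate to
  slightly smaller Spearman values ((6/π)·asin(ρ/2), e.g. 0.582 for
  ρ = 0.6), which is visible in recovery experiments.
* Within-block associations are out of scope by design, as are group
  comparisons and any causal or formal mediation analysis: "indirect"
  here is a graph-topological statement, not a mediation estimate.
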