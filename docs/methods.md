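# Methods

## Model

The nodal variable is the cerebral metabolic rate for glucose (CMRgl):
mean FDG-PET uptake of each of 90 anatomical regions (AAL parcellation),
one value per subject per region. An edge weight between two regions is
the Pearson correlation of their uptake **across subjects**; the network
is therefore a group-level object, one per clinical group (NC, MCI, AD),
not a per-subject network. Edges summarize symmetric covariation — they
carry no directionality and no within-subject temporal information, so no
causal reading is possible. Partial correlations are deliberately not
used: with 90 regions and fewer than 90 subjects per group the precision
matrix is not estimable.

Pipeline stages and their assumptions:

1. **Reference normalization.** Uptake is divided by the subject's
   brainstem mean. Global-mean scaling would shrink patient/control
   differences because whole-brain metabolism itself is reduced in
   disease; the brainstem is comparatively preserved. The operation is
   scale-equivariant: multiplying a subject's uptake and reference by a
   common factor changes nothing downstream.
2. **Covariate screen.** Education is tested region-by-region by simple
   regression before entering the confound model; it is kept only if some
   region is significant. The keep/drop decision uses Bonferroni-corrected
   marginal p-values over the 90 regions so that a covariate with no real
   effect is dropped in about 95% of cohorts; with raw p-values a null
   covariate would be retained almost always (1 − 0.95⁹⁰ ≈ 0.99), which
   would make the screen pointless. Raw per-region p-values are reported;
   `bonferroni=False` restores the raw-threshold rule.
3. **Confound regression.** Per region, OLS residuals of uptake on
   intercept, centered age, sex (M=0/F=1), centered-age × sex, total
   uptake (the sum over the 90 regions, computed after normalization) and
   the region's own volume (a partial-volume proxy). The volume column is
   region-specific, so the fit is region-wise. Residuals replace the raw
   matrix. For the connectivity stage the regression is fitted within each
   group's subjects; the regional group contrasts instead fit one pooled
   model with group indicators and test pairwise group contrasts with the
   classical pooled-variance t statistic, Bonferroni-corrected over the 90
   regions within each contrast.
4. **Connectivity and binarization.** Pearson matrices with a zero
   diagonal; Nboot = 300 bootstrap matrices from random 80% subject
   subsets, drawn without replacement within a sample and independently
   across samples (`replace=True` switches to with-replacement draws). A
   binary graph at sparsity degree s keeps the K = ⌊(1−s)·N(N−1)/2⌋ pairs
   of largest absolute correlation; the floor guarantees realized sparsity
   is never below nominal (at s = 0.9, K = 400 of 4005). Ties at the
   threshold are broken by atlas pair order via a stable sort, which also
   makes the edge sets nested along the grid. The default grid is
   s = 0.5 … 0.9 in steps of 0.02 (21 values).
5. **Graph attributes.** Standard unweighted, undirected conventions:
   clustering index C_i with C_i = 0 for degree < 2 and C = mean over all
   nodes; characteristic path length L = mean geodesic over connected
   ordered pairs (a strict mode errors on disconnection instead); global
   efficiency = mean inverse geodesic with 1/∞ = 0; local efficiency =
   mean over nodes of the global efficiency of the neighbor-induced
   subgraph (nodes of degree < 2 contribute 0); betweenness with
   fractional credit across equally short paths. Small-worldness
   σ = (C/C̄_rand)/(L/L̄_rand) against an ensemble (default 100) of
   Maslov–Sneppen rewired graphs — repeated double-edge swaps, 10·K
   attempted per draw, rejections skipped — which preserve the degree
   sequence exactly; σ is computed on the largest component when the
   graph is fragmented. Standard metrics are delegated to networkx; tests
   verify them against independent brute-force oracles (matrix-power
   triangle counts, Floyd–Warshall distances, exhaustive geodesic
   enumeration) exhaustively on all labeled graphs up to 5 nodes, on the
   full graph atlas up to 7 nodes, and on random graphs up to 25 nodes.
6. **Group statistics.**
   - Edge-wise: Fisher z = arctanh(r), Z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)),
     two-sided normal p, Benjamini–Hochberg at q = 0.05 over the 4005
     pairs. Group sizes n₁, n₂ are the full-sample sizes and the
     full-sample matrices are compared (not bootstrap aggregates).
   - Global attributes: the per-bootstrap area under the attribute–
     sparsity curve (trapezoidal), compared across groups by
     Kruskal–Wallis with pairwise two-sided Mann–Whitney post hoc tests,
     Bonferroni ×3. Bootstrap AUCs are treated as exchangeable samples;
     the resulting p-values describe bootstrap-distribution separation,
     not subject-level inference, and are labeled as such in outputs.
   - Nodal NBC: b_i = B_i/⟨B⟩ computed per bootstrap and grid point, but
     only up to the largest grid sparsity at which **every** bootstrap
     graph of every group is fully connected (edge-set nesting makes
     connectivity monotone, so one scan suffices). Per region and grid
     point a KW test across groups, Bonferroni over the 90 regions (not
     90×21: the ≥99% rule already integrates over the grid); a region is
     declared different only if corrected-significant at ≥ 99% of usable
     grid points. Hubs are regions with grand-mean NBC (over bootstraps
     and usable grid points) strictly above 1.5.
   - Spatial: counts of the top-1000 |r| edges falling within each of the
     five named lobes (Frontal, Temporal, Occipital, Limbic, Parietal;
     central-strip and subcortical regions count only toward cross-lobe
     edges), intra-lobe mean |r|, the Core set (bilateral precentral,
     supplementary-motor, median-cingulate, postcentral, paracentral)
     versus itself and versus Frontal/Limbic with Core members removed
     from the target lobes, and mean |r| within a hypometabolic region
     set — each per bootstrap, KW across groups.

## Atlas and lobe taxonomy

The shipped table lists the 90 AAL regions in standard order
(left/right interleaved), with hemisphere and lobe labels. Lobes are the
five named lobes plus two catch-alls — `Central` (precentral, postcentral,
rolandic operculum) and `Subcortical-nuclei` (amygdala, caudate, putamen,
pallidum, thalamus) — so that every region is assignable. The insula is
grouped with the limbic lobe (the common limbic/paralimbic grouping; the
source taxonomy lists it as its own one-member category). Fusiform is
occipital; the temporal poles are limbic. Homologous pairing is by
abbreviation stem (`PreCG.L`/`PreCG.R`) and must be a bijection between
hemispheres.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` draw each group from a multivariate normal
whose correlation matrix is assembled from three levels — homologous
pairs at 0.7, within-lobe blocks at 0.4, background 0.1 — with optional
explicit edge overrides, then repaired to positive semi-definite by
eigenvalue clipping and diagonal rescaling (a repair moving any entry by
more than 0.05 is an error: the requested structure is infeasible). Group
means are a common baseline (1.2 units, regional SD 0.1) minus planted
fractional reductions; defaults plant an AD hypometabolic set of 15
temporo-parietal/limbic/occipital regions at 15% and an MCI subset of 6
regions at 7%, echoing the qualitative clinical pattern (magnitudes are
chosen for test power; the underlying studies do not quantify them).
Covariates: age ~ U(55, 90), sex ~ Bernoulli(½), volumes ~ lognormal;
linear age/sex/age×sex/volume effects are added to the latent uptake, and
the emitted raw uptake is multiplied by a positive per-subject brainstem
reference so that normalization recovers the structured matrix. Per-group
RNG streams are derived from (seed, group), so adding a group never
perturbs the others. Default group sizes are 68/62/69 (NC/MCI/AD).

What the generator does **not** emulate: PET physics and partial-volume
effects beyond a volume covariate, non-Gaussian tails, spatially smooth
noise, site/scanner batch effects, and longitudinal drift. Passing tests
on synthetic cohorts therefore validate the statistical machinery under
the stated second-order structure, not the biological findings
obtainable from real imaging tables.

## Numerical choices

- Edge-count rounding is `floor`; realized threshold R_k (smallest
  retained |r|) is recorded on every binary graph.
- Covariance repair: eigenvalues clipped at 0, diagonal rescaled to the
  target variance; repairs are logged.
- K = 0 after flooring, a constant residual column, |r| ≥ 1 in the Fisher
  transform, n ≤ 3 in the Z comparison, and a fully tied KW input are all
  explicit errors or short-circuits (tied KW reports p = 1, no post hoc).
- Degenerate NBC (mean betweenness 0, e.g. complete graphs) raises rather
  than silently returning zeros.
- A single root seed deterministically spawns per-stage seeds
  (SHA-256 of `seed:stage`), so (config, seed) fixes every output byte.

## Calibration notes and limitations

- The Fisher/Z edge comparison is calibrated at the operation level:
  with two groups drawn from an identical covariance (n = 150/group, 30
  regions), the mean false-discovery proportion over 500 simulations is
  ≈ 0.04 ≤ q = 0.05. Feeding the comparison matrices of confound-
  **regressed** residuals instead raises the measured null rate to
  ≈ 0.06–0.07: the regression absorbs ~6 degrees of freedom and the
  total-uptake regressor couples the columns, so 1/(n−3) slightly
  understates the z variance. This mild anti-conservatism is a property
  of the procedure itself; passing effective sample sizes (n − 6) via the
  `n1`/`n2` arguments removes about half of it.
- KW on bootstrap AUCs is calibrated only under exchangeable bootstrap
  ensembles (same subject pool). Ensembles from different finite samples
  of the same population will separate as Nboot grows; the reported
  p-values must be read as descriptive of bootstrap separation.
- Test and acceptance runs use scaled-down problem sizes chosen as the
  package's own defaults for simulation studies: 300–500 null replicates
  at 30 regions for calibration, 10–20 seeds for recovery studies,
  bootstrap ensembles of 8–20 for planted-effect checks, and rewiring
  ensembles of 100 for σ. The planted-hub scenario uses a 12-edge star at
  r = 0.28 with n = 400 subjects — star strength is bounded by positive
  semi-definiteness (a node cannot correlate strongly with many mutually
  uncorrelated nodes), so hub prominence is driven by bridging position
  rather than raw edge weight.
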