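# Methods

## The analysis model

`subscn` implements a group-level structural covariance network (SCN)
analysis for subcortical gray-matter volumes, together with the volumetric
group-comparison statistics that usually accompany it.

The object of study is not a per-participant network.  For each diagnostic
group (currently depressed `cMDD`, remitted `RD`, healthy control `HC`), a
single 100 x 100 association matrix is formed whose entry (i, j) is the
Pearson correlation, **across the group's participants**, of the
covariate-adjusted volumes of ROIs i and j.  Covariance of regional
morphometry is read as a signature of coordinated development and
connectivity; differences in the topology of the thresholded covariance
graph between groups are the quantity of interest.

### Covariate adjustment

Each ROI volume is residualized on `[1, age, ICV]` by ordinary least
squares; all networks are built on these residuals.  Covariates are
mean-centered before fitting (conditioning only; residuals are invariant
to affine rescaling of covariates, and residualization is idempotent —
both are enforced by tests).  Three fitting scopes are exposed:

* `pooled_pair` (default for comparisons): one regression over the two
  groups being compared, fitted once before permutation.  Correction must
  precede the permutation scheme — relabelled participants carry their
  corrected volumes with them — and pooled fitting keeps the two groups
  exchangeable under the null.
* `pooled_all`, `per_group`: sensitivity variants.  Whether the original
  analyses pooled or fitted per group is not determinable from the
  published description, hence the explicit knob rather than a silent
  choice.

### Network construction

Edges are defined by density thresholding: at density `d`, the
`floor(d * N(N-1)/2)` node pairs with the **largest signed correlation**
become edges of an undirected, unweighted graph.  Signed (not absolute)
ranking is the default, following the positive-covariance convention of
the graph-analysis toolboxes this lineage of studies uses; absolute
ranking is available as a flag on nothing-up-my-sleeve grounds but is not
used anywhere.  Ties are broken by lexicographic pair order so edge sets
are bit-reproducible.  Density, not a raw correlation cut-off, is used so
that group networks are compared at matched edge count.

The analysis sweep covers densities 0.17 to 0.45 in steps of 0.02
(15 networks per group).  A minimum-density utility reports the smallest
grid density at which the graph is one connected component; networks that
fragment inside the sweep are flagged, and path-length-based quantities
refuse flagged networks rather than silently imputing.

### Topological properties

Global: mean Watts–Strogatz clustering C (degree < 2 contributes 0),
characteristic path length L (mean shortest path over ordered pairs;
connected graphs only), global efficiency E_glob (mean inverse shortest
path, 1/inf = 0, so fragmentation is tolerated), modularity Q, and the
small-world indices gamma = C/C_rand, lambda = L/L_rand,
sigma = gamma/lambda, with sigma > 1 read as small-world organization.

The random reference for gamma/lambda is an ensemble of degree-preserving
rewired graphs (double-edge swaps, 10x the edge count of swap attempts,
redrawn until connected when the input is connected; 20 references by
default).  The reference ensemble is a convention choice the source
description leaves open; degree-preserving rewiring is the standard in
this literature and is what keeps gamma/lambda comparable across groups
with different degree sequences.

Modularity is maximized by a randomized greedy agglomerative optimizer:
communities start as singletons; each step merges the connected pair with
the largest modularity gain (uniform choice among near-ties, and among the
top 3 candidates on restarts after the first, to diversify the search),
tracking the best partition along the full merge trajectory; a
single-node-move refinement pass follows; the best result over `n_iter`
restarts (default 1000) is returned.  The optimizer never returns Q below
the single-community baseline of 0.  On all connected graphs of <= 7
nodes it reaches the exhaustive-enumeration optimum (tested over the
complete non-isomorphic atlas).

Nodal: degree, local clustering, and Brandes betweenness normalized by
(N-1)(N-2)/2.

Degree distributions are summarized by a nonlinear least-squares fit of
the empirical cumulative distribution P(K >= k) to
`c * k^(a-1) * exp(-k/b)` — a power law with exponent `a` truncated by an
exponential cut-off at degree `b`.  The free multiplicative constant `c`
absorbs the normalization of the empirical curve; `a`, `b` and the
curve-level R^2 are reported.  The fit is computed on the network at the
lowest analyzed density by default (one fit per group is conventionally
reported without a density; the density is exposed as an argument).
Initialization is the log-linearized least-squares solution; a regular
graph (fewer than 5 distinct degrees) is rejected rather than fitted.

Resilience: random-failure curves — remove a fraction of nodes uniformly
at random, record the largest connected component relative to the original
node count, average over repetitions (default 100).

### Permutation inference with an across-threshold statistic

Group comparisons are non-parametric.  The pooled, covariate-corrected
residuals of the two groups are relabelled into random pseudo-groups of
the original sizes (default 1000 repetitions); each relabelling rebuilds
both association matrices and both density sweeps and recomputes every
metric at every density.  One relabelling schedule is shared by all
metrics of a comparison, preserving cross-metric coherence.

Per density, the two-tailed p-value is the add-one percentile
`p = (1 + #{|null diff| >= |observed diff|}) / (n_perm + 1)` — never zero,
floor 1/(n_perm+1).  The across-threshold ("functional data analysis")
statistic is the signed area between the two metric-versus-density curves,
i.e. the sum of per-density differences, tested by the same percentile
rule against its own permutation distribution.  The signed sum is the
simplest functional consistent with comparing whole curves across
thresholds; two-tailed testing is used throughout (`permutation_test`
accepts `tails="greater"/"less"` for sensitivity work, and
`binarize_at_density` accepts `rank_by="absolute"` for the |r|-ranking
variant; neither is used by the defaults).

If a pseudo-group's network fragments at a low density, that replicate's
path-dependent metrics are recorded as missing at that density;
per-density p-values then use complete-pairs counting and the FDA sum
runs over the densities observed for that replicate.  Missingness is
counted and logged loudly.

Nodal comparisons compute a per-node FDA p-value for degree, clustering
and betweenness and apply Benjamini–Hochberg FDR across the 100 nodes,
per metric; raw and adjusted decisions are both reported.

### Volumetric and demographic statistics

* Omnibus MANCOVA: Wilks' lambda for the group effect on all ROI volumes
  with age and ICV as covariates, computed as det(E)/det(E+H) from
  residual SSCP matrices of the full and covariates-only models, with
  Rao's F approximation.  The multivariate partial eta-squared convention
  `1 - lambda^(1/s)` is used and recorded in the result.  The design
  needs more participants than DVs + parameters (n > ~104 at 100 ROIs);
  smaller cohorts are refused with a pointer to the per-ROI arm.
* Per-ROI ANCOVA F for group, BH-FDR across ROIs; for FDR-surviving ROIs,
  covariate-adjusted pairwise contrasts (t on the group dummy of a
  two-group OLS).  The FDR gate sits at the ROI level, not the contrast
  level.  A "trait" marker shows both patient-vs-control contrasts
  significant and the patient-vs-patient contrast not; a "state" marker
  shows exactly one patient-vs-control contrast.
* Demographics: Pearson chi-square without continuity correction
  (gender x group), one-way ANOVA (age, education, rumination score),
  Kruskal–Wallis (depression score), Mann–Whitney U (illness duration
  between the two patient groups).
* ROI–psychometric correlations: Pearson for rumination and
  illness-remission scores, Spearman for depression score and illness
  duration, pairwise deletion of missing clinical values, two-tailed p.

## The synthetic cohort generator

No volumetric dataset accompanies this line of work, so the generator is a
first-class module: every downstream stage is exercised on cohorts whose
ground truth is known.

The generative model per participant p, group g, ROI i:

    v_pi = base_i + marker(g, i) + beta_age_i (age_p - mean age)
           + beta_icv_i (icv_p - mean icv) + (Lambda_g f_p)_i + eps_pi

with standard-normal latent factors and independent Gaussian noise.
Loadings are specified in noise-sd units and variance-normalized so each
ROI's marginal sd is 12% of its base volume — correlations are then set
by loading ratios alone, and small nuclei (a few mm^3) never draw
negative volumes.  Base volumes are FreeSurfer-typical per structure; age
slopes are -0.2%/year, ICV slopes scale volumes by head size.  Marker
effects are additive mean shifts that leave covariance untouched, so the
volumetric arm and the SCN arm can be probed independently — deliberately
mirroring the fact that these are separate findings in the literature.

Shipped specifications (all deterministic given a seed):

* `paperlike_spec` — 131/67/235 over the 100-ROI catalog.  The control
  group has seven anatomical modules (bilateral basal ganglia; amygdala,
  hippocampus, thalamus per hemisphere) with graded within-module
  loadings (1.4/1.1/0.75/0.45 cycling) plus a 0.65 global factor; the
  grading lets between-module edges enter the density ranking early, so
  the control network typically connects by density ~0.17 (median over
  seeds), matching the analyzed range.  Patient groups have the same
  modules scaled by 0.68 (remitted) and 0.5 (currently depressed) with
  stronger global factors — flatter, less differentiated covariance and
  hence lower clustering and small-worldness at matched density.
  Demographics and clinical scores follow the published group profiles;
  marker shifts plant the bilateral pallidal / thalamic trait-and-state
  pattern with the published mean differences.
* `tiny_spec` — the same design at 30/30/30 over a 20-ROI reduced catalog,
  for fast tests.
* `null_pair_spec` — two groups drawn from one identical law (weak global
  factor only), for type-I-error calibration.
* `contrast_pair_spec` — the planted-effect pair used in power checks:
  controls as above; patients carry a sparse sequential lattice covariance
  (one factor per adjacent pair of a 4 x 5 grid, plus a weak global
  factor).  The lattice has few triangles and no integrative modules, so
  the patient network is markedly less clustered and less small-world —
  the qualitative deficit direction of interest.

**A deliberate limitation of the planted path-length contrast.**  At 20
nodes and matched density, absolute path length and clustering are
positively coupled through edge concentration: construction experiments
showed that every covariance structure lowering patient clustering also
shortened (or left unchanged) the patient path-length curve.  The shipped
contrast therefore separates the two L curves cleanly but with the
patient curve the *shorter* one; the two-tailed across-threshold test
flags the difference regardless of sign.  Reproducing the
longer-absolute-path patient pattern seen at 100 nodes would need larger
networks than these desk-scale checks use.

What the generator does **not** emulate: segmentation error and site
effects, non-Gaussian or heavy-tailed volume distributions, lateralization
beyond the planted markers, age-by-group interactions, and any spatial
autocorrelation beyond the planted factor structure.  Passing tests show
the pipeline recovers known structure from data satisfying its model
assumptions; they say nothing about robustness to violations of those
assumptions in real morphometry.

## Numerical and design choices

* Exact edge count per density is `floor(d * N(N-1)/2)`; achieved density
  is recorded and is within one pair of the request.
* All stochastic operations take explicit seeds; the pipeline derives
  per-stage substreams from one master seed via CRC32-keyed
  `SeedSequence` spawn keys, so stages are independent and reorderable.
* Shortest paths use a BFS kernel JIT-compiled with numba (pure-Python
  fallback with scipy's csgraph when numba is unavailable); the
  double-edge-swap kernel is likewise JIT-compiled.  Identical semantics
  either way, enforced by the oracle tests.
* Degenerate inputs fail loudly: zero-variance ROIs (undefined
  correlation), fragmented graphs for L, regular graphs for the degree
  fit, rank-deficient covariate designs, MANCOVA with too few
  participants.
* Scaled problem sizes in the test suite and the acceptance script
  (e.g. 100–200 permutations, 3–20 random references, 30–200 simulated
  datasets, 20-ROI cohorts) are the package's own desk-scale defaults for
  validation runs; the pipeline defaults (1000 permutations, 20
  references, 1000 modularity restarts, full catalog) match the
  full-scale analysis.

## Known limitations

* The exact 100-ROI name list follows the FreeSurfer 7 atlas families
  (4 basal-ganglia structures, 9 amygdaloid nuclei, 12 hippocampal
  subfields, 25 thalamic nuclei per hemisphere) but ships as an editable
  TSV: the hippocampal set splits CA2 and CA3 (merged in FreeSurfer's
  output) to honor the stated count of 12 gray-matter subfields; users
  with their own naming can edit the catalog file and the alias map.
* Weighted, partial-correlation and sparse-inverse-covariance networks
  are out of scope (partial correlations are not estimable with more
  ROIs than participants, which is exactly the regime here).
* No targeted-attack resilience, no local efficiency, no three-group
  omnibus permutation test — comparisons are pairwise.
* The FDA functional is the signed area; other functionals (max deviation,
  integrated squared difference) are not implemented.
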