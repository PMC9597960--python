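# Methods

This note documents the models, parameters, and design decisions behind
`scflux`, and what the synthetic studies can and cannot demonstrate.

## Pipeline model

The feasible flux set of a constraint-based model is the polytope
{**v** : S·**v** = 0, **v**_L ≤ **v** ≤ **v**_U}. All LP work (FVA, FBA,
knockouts) is delegated to cobrapy with the GLPK solver; flux variability
analysis does not fix the objective at any fraction of its optimum, so the
envelopes describe the whole steady-state polytope under the growth medium.

**Growth medium.** "Rich medium" opens every exchange reaction's uptake
direction to a finite magnitude (default 1000 flux units, e.g.
mmol·gDW⁻¹·h⁻¹) rather than infinity, keeping all LPs bounded. Sign
convention: uptake is negative exchange flux, secretion positive.

**Reaction Activity Scores.** GPR strings are parsed with AND binding
tighter than OR and parentheses overriding; the rule tree is evaluated
numerically with min over AND and sum over OR. A *measured zero is a
number*; only genes absent from the expression matrix are treated as
missing and dropped from their operator (a node whose children are all
missing is itself missing). Matching between the model's gene namespace
and the matrix is exact-string, with an optional user mapping table for
cross-namespace datasets. Reactions whose genes are all absent are dropped
from the RAS matrix and reported, together with a gene-coverage fraction.

**RAS-derived bounds.** The per-reaction normaliser max_c RAS_j^c is taken
over the cells of the current run, so bounds are invariant to rescaling any
single reaction's scores. A reaction whose RAS is zero in every cell keeps
bounds (0, 0). The ε-strategy's lower-bound formula is applied exactly as
defined, which for irreversible reactions (F_j^l = 0) yields slightly
negative lower bounds at sub-maximal RAS; affected reactions are flagged on
the bounds object rather than silently clamped (clamping only enforces
L ≤ U when ε exceeds an envelope). Bounds are applied to GPR-bearing
internal reactions only; exchanges keep medium bounds, GPR-less internal
reactions keep their FVA envelope.

**Per-cell FBA.** The optimal vertex of an LP is not unique, and clustering
on arbitrary vertices would be solver-dependent. The reported vector is
pinned by a parsimonious tiebreak: the objective is fixed at its optimum
and Σ|v| minimised (pFBA). Infeasible cells are recorded with NaN fluxes
and an `infeasible` status, never raised. Essentiality (knockout → optimum
≤ 10⁻⁹) is computed once on the rich-medium model, not per cell.

**Flux QC.** Cells with RAS ≤ 10⁻⁹ on at least one essential GPR-bearing
reaction are removed before clustering: their objective flux is forced to
zero, usually by a dropout artefact rather than biology.

**Clustering.** Features (genes for the transcript path, reactions for the
flux path) are z-scored; fluxes are *not* log-transformed. For each grid
point (n_pcs ∈ {5, 10, 15, 20} × resolution ∈ {0.1, 0.25, 0.5, 1.0}) the
cells are PCA-reduced, a symmetrised kNN graph built, and Leiden run
(seeded, 2 iterations); the grid point with the best silhouette in its own
PCA space wins, single-cluster partitions being excluded from selection.
Ties resolve to the first grid point in order, so selection is
deterministic under a fixed seed. The graph degree `neighbors_k` is capped
at n_cells − 1 when a QC-filtered run retains few cells.

## Diffusion denoiser

Cells are embedded by PCA (default 20 components), a kNN graph built
(default knn = 15), affinities set by an adaptive Gaussian kernel
exp(−(d/σ_i)^decay) with σ_i the distance to the knn-th neighbour and
decay = 1, symmetrised, and row-normalised into a Markov matrix P. The
denoised matrix is P^t · (cells × features) with t = 3 by default; t = 0 is
admitted as the identity for testing. Output rows are convex combinations
of input rows, so nonnegativity and per-feature ranges are preserved; a
zero can survive only if an entire diffusion neighbourhood is zero. The
same operator applies to the RAS matrix, reactions playing the role of
genes.

**Distance scale.** The transform applied before PCA is configurable
(`distance_scale`): `cosine` (default; L2-normalise each cell profile),
`linear`, or `log1p`. The default makes the similarity graph invariant to
residual per-cell scale that total-count normalisation cannot remove when
zeros are inflated. `log1p` is deliberately not the default: under
zero-inflation that is independent of expression level, a dropout flips a
log-coordinate by the full log-magnitude of the value, and these flips
swamp fold-change structure; on the synthetic fixture a log-space graph
destroys the planted 5× population contrast of the branch scores (reducing
it to ~1.1×) while cosine/linear preserve it.

**Neighbourhood size is an analysis choice, not a constant.** Two distinct
properties are measured on denoised data and they favour different
neighbourhood scales. Recovering *local* structure — e.g. the correlation
between two co-regulated genes — requires neighbourhoods small enough that
the program's gradient survives smoothing: the package default knn = 15.
Recovering *population* structure in downstream flux clustering requires
neighbourhoods at the scale of the populations themselves (knn ≈ half a
population, here 45): smaller neighbourhoods leave smoothed sampling noise
that is lumpy at the graph-community scale, and the silhouette-selected
Leiden step then carves each population into spurious (but pure)
sub-clusters. `synthetic_data.fixture_analysis_configs()` returns the
population-scale settings matched to a fixture (diffusion knn and a denser
clustering graph, neighbors_k = 40 at 100 cells/population). Real data
with unknown population sizes faces the same trade-off; the choice is
exposed rather than hidden.

External denoisers (MAGIC, ENHANCE, SAVER) are adapters only: they
round-trip a matrix through the installed tool with its defaults and
enforce shape preservation, raising an actionable error with an install
hint when the tool is absent.

## Preprocessing defaults

- QC filter: cells with < 2000 detected genes are removed first, then genes
  detected in < 3 surviving cells. The order is fixed because it changes
  which genes survive. (Synthetic fixtures use a lower cell threshold
  matched to their gene-panel size.)
- Total-count normalisation to 10⁶ per cell (CPM-style; no gene-length
  term), then log1p where a log layer is required.
- Cell-cycle scoring: per signature, mean expression minus the mean of a
  control set matched on 25 expression bins with 50 controls per signature
  gene, seeded; phase = G1 when both scores ≤ 0, otherwise the larger
  score's phase. Scoring runs on the log-normalised layer via scanpy's
  binned-control implementation behind this module's interface.

## Synthetic data generator

The generator plants known structure in an otherwise realistic count
matrix; its defaults are the study conditions for the acceptance checks.

- **Counts.** Gene- and population-specific means, scaled per cell by a
  lognormal library size (σ = 0.25), drawn negative-binomially with
  dispersion θ = 10 (var = μ + μ²/θ), then zeroed independently with
  probability 0.4. Independent (expression-level-free) dropout is the
  default because it makes the acceptance arithmetic exact (observed zero
  fraction = truth + 0.4·(1 − truth)); a mean-dependent logistic variant is
  available but non-default.
- **Populations.** Two populations of 100 cells on the `branched` toy
  network: trunk genes at mean 15 in both; branch-B genes 5× up in `popA`
  (15 vs 3), branch-C genes 5× up in `popB`. 300 decoy genes with a flat
  lognormal mean distribution (log-mean log 10, log-sd 0.4) provide
  whole-transcriptome context; 100 of them form a bidirectional marker
  panel (50 up 4× in each population), so cell identities differ
  transcriptome-wide without skewing total counts. A flat mean profile is
  deliberate: a handful of very-high-mean genes would each contribute a
  dominant dropout axis to the PCA space the denoiser works in.
- **Co-regulated program.** A bivariate lognormal factor (log-sd 1.2)
  drives the dedicated genes PRGA/PRGB (mean 20) plus a 16-gene decoy
  block, half activated and half repressed by the same latents so the
  program is visible to the similarity graph while leaving totals
  mean-neutral. The latent correlation is chosen so the *observed*
  pre-dropout Spearman hits its 0.8 target: the bivariate-normal relation
  ρ_s = (6/π)·asin(r/2) combined with classical measurement-error
  deattenuation, using the exact conditional variance of log(X + ½) under
  NB sampling (Gauss–Hermite quadrature over the factor) rather than the
  delta-method approximation, which underestimates small-count skew.
  Across seeds the realised pre-dropout correlation is 0.78–0.83.
- **Toy models.** `chain3` is a three-reaction uptake→conversion→sink chain
  (every reaction essential). `branched` has an essential two-reaction
  trunk feeding two parallel routes of different length (2 vs 3 steps, so
  the parsimonious tiebreak deterministically prefers the short route), one
  GPR of each class (single, OR-only, AND-only, complex), and a GPR-less
  objective sink capped at 0.3× the internal bound. The low sink cap makes
  the achievable optimum a model constant well below trunk and branch
  capacities: what distinguishes cells in flux space is *which route*
  carries the flux, not a noisy per-cell magnitude. Without this, the
  RAS-scaled trunk capacity forms a pure-noise axis that per-reaction
  z-scoring amplifies to the same scale as the population gap.
- **Cell cycle (optional).** Phase labels drawn per cell
  (G1/S/G2M = 0.6/0.2/0.2) with 20 dedicated signature genes per phase
  upshifted 8× in their phase.

**What passing the synthetic checks does and does not show.** The fixture
has exactly two, strongly separated, internally homogeneous populations;
real datasets have continuous substructure, mean-dependent dropout, batch
effects and ambient RNA, none of which are modelled. Success here shows the
machinery is correct and that denoising repairs the specific failure mode
it targets (essential-reaction false zeros); it does not calibrate
performance on real tissues. Problem sizes (200 cells, ~330 genes, a
9-reaction network) were chosen so the full study, including two complete
pipeline passes, runs in seconds while keeping every statistical
contrast several standard errors wide.

## Numerical choices

- LP feasibility/essentiality/zero-RAS tolerance: 10⁻⁹ absolute; steady
  state verified to ‖S·v‖∞ < 10⁻⁶ on reported flux vectors.
- FVA envelopes are snapped to min ≤ max when LP round-off inverts a
  degenerate envelope by < 10⁻⁶.
- Duplicate gene identifiers are collapsed by summing counts at read time
  (and after namespace mapping), before any GPR evaluation.
- Every stochastic step (control-gene sampling, PCA solvers, Leiden,
  simulation) takes an explicit seed; pipeline reruns from the same config
  are bit-identical, which the manifest checksums assert.

## Known limitations

- The ε-strategy as defined can yield slightly negative lower bounds for
  irreversible reactions; flagged, not corrected.
- Leiden + silhouette model selection can report legitimate substructure
  within a population (pure splits); on noisy fixtures this lowers ARI
  without lowering purity. The population-scale neighbourhood settings
  mitigate but cannot abolish this on arbitrary data.
- The external-denoiser adapters execute tools with their own defaults,
  which are version-dependent; results obtained through them are not
  pinned by this package's seeds.
- Essentiality is evaluated on the rich-medium model once; condition-
  specific essentiality (per-cell media) is out of scope.
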