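# scflux

Single-cell flux balance analysis with denoised Reaction Activity Scores.

`scflux` estimates a metabolic flux distribution for every cell in a
scRNA-seq experiment and clusters cells on those fluxes. It is aimed at
computational biologists who want to stratify a mixed cell population by
*metabolic phenotype* — something transcript-level clustering does not give
directly — using nothing more than a counts matrix and a constraint-based
metabolic model.

The central obstacle is dropout: scRNA-seq false zeros propagate into the
reaction-level scores and switch off reactions that are essential for the
FBA objective, so naïvely constrained models predict zero growth for almost
every cell. `scflux` therefore builds graph-diffusion denoising into the
pipeline (applicable to the counts or directly to the score matrix) and
quantifies, on data with known ground truth, how much of the metabolic
signal denoising recovers.

## Method

For a model with stoichiometric matrix **S** (M metabolites × R reactions),
flux bounds **v**_L ≤ **v** ≤ **v**_U and boolean gene–protein–reaction
rules, the pipeline computes per cell *c*:

1. **Reaction Activity Scores.** For reaction *j* with gene set *G_j*,
   RAS_j^c is the GPR evaluated numerically on (denoised, total-count
   normalised) transcript abundances *T_g^c*: AND → min (enzyme complexes
   are limited by their scarcest subunit), OR → sum (isoenzymes add
   capacity); genes missing from the matrix are dropped from their
   operator (`A AND missing` = `A`).
2. **Flux bounds.** With [F_j^l, F_j^u] the FVA envelope of reaction *j*
   under a rich medium and r = RAS_j^c / max_c RAS_j^c,

   - plain strategy: U_j^c = F_j^u · r, L_j^c = F_j^l · r
   - ε-strategy: U_j^c = ε + (F_j^u − ε) · r, L_j^c = −ε + (F_j^l + ε) · r
     (default ε = 0.01, leaving residual capacity at zero RAS)

   Reactions without a GPR keep their envelope; exchange reactions keep
   the medium bounds.
3. **Per-cell FBA.** max v_obj subject to S·**v** = 0 and the cell's
   bounds, with a parsimonious tiebreak (minimise Σ|v| at the optimum) so
   the reported vertex is unique and reproducible.
4. **QC and clustering.** Cells with a zero RAS on any reaction essential
   for the objective are removed (they cannot grow); the remaining
   reactions × cells flux matrix is z-scored, PCA-reduced and clustered
   with Leiden, selecting (number of PCs, resolution) by silhouette.

The in-repo denoiser is a diffusion smoother: a kNN graph over cells in
PCA space, an adaptive Gaussian kernel, row-normalisation to a Markov
matrix P, and imputation by P^t · (cells × genes). MAGIC, ENHANCE and
SAVER are available as thin adapters when installed.

## Worked example

Simulate a two-population dropout dataset on the bundled branched toy
network and run the full pipeline (population-scale denoising
neighbourhoods; see `docs/methods.md`):

```python
import scflux as sf

bundle = sf.end_to_end_fixture("branched", seed=1)
cfg = sf.RunConfig(outdir="run", min_genes_per_cell=50,
                   denoise_stage="on_counts", seed=1,
                   diffusion={"knn": 45, "t": 3, "seed": 1},
                   cluster={"neighbors_k": 40, "seed": 1})
outdir = sf.run_pipeline(cfg, model=bundle.model, counts=bundle.counts)

import json
meta = json.load(open(outdir / "run_metadata.json"))
print(f"cells in / after QC filter / after flux QC: "
      f"{meta['n_cells_in']} / {meta['n_cells_after_qc_filter']} / {meta['n_cells_after_flux_qc']}")
print(f"RAS zero fraction: {meta['ras_zero_fraction']:.4f}")
print(f"essential reactions: {meta['essential_reactions']}")
print(f"clusters: {meta['n_clusters']} (n_pcs={meta['selected_n_pcs']}, "
      f"resolution={meta['selected_resolution']}, silhouette={meta['silhouette']:.3f})")
print(f"ARI vs planted populations: {meta['ari_vs_known']:.2f}")
```

prints

```
cells in / after QC filter / after flux QC: 200 / 200 / 200
RAS zero fraction: 0.0000
essential reactions: ['BIOMASS', 'EX_A', 'R_TRK', 'T_A']
clusters: 2 (n_pcs=5, resolution=0.1, silhouette=0.694)
ARI vs planted populations: 1.00
```

With denoising, no cell has a zero score on an essential reaction (the QC
rule removes 0 of 200 cells) and flux clustering recovers the two planted
metabolic programs exactly (adjusted Rand index 1.0). Re-running the same
config with `denoise_stage="none"` removes ~80% of the cells at QC and
drops the ARI to ≈ 0 — the dropout problem the pipeline exists to fix.

The same stages are exposed on the command line (`scflux simulate`,
`scflux preprocess`, `scflux ras`, `scflux bounds`, `scflux run
--config run.yaml`, …); `scflux model summary model.tsv` prints the
reaction/metabolite/gene counts and the GPR class census of a model file.

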