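# tslniche

Quantitative machinery for studying how antigen-presenting dendritic-cell
niches in the tumour-draining lymph node (tdLN) maintain high-avidity
stem-like CD8+ T cells (T_SL, TCF-1+), and what PD-1 checkpoint blockade does
to them. The package bundles three analysis layers behind one library/CLI:

1. **3D histocytometry** — turn multi-channel lymph-node volumes plus nuclear
   segmentation masks into per-cell feature tables: spillover compensation
   and depth-attenuation correction, collision-free membrane-mask expansion,
   masked mean intensities, polygon gating, z-score heatmap matrices, and
   spatial niche statistics (per-slice Gaussian cDC1 density, NFAT
   nuclear/membrane translocation ratio, weighted 3D Gaussian KDE maps).
2. **Imputed TCR affinity** — the per-cell tetramer/CD3 staining ratio as a
   receptor-level-normalised proxy for TCR–pMHC affinity, with cohort
   z-standardisation against control-IgG SLAMF6+ T_SL cells, normalised mean
   ratios, a positivity translation for log transforms, and equal-frequency
   quantile binning.
3. **Hierarchical Bayesian models** — two Gaussian multilevel models (cellular
   z(log affinity); standardized per-mouse log cell counts) regressed on
   cell state × treatment with per-mouse random intercepts and state slopes,
   fitted by a blocked Gibbs sampler; population-level posterior prediction
   and the expected high-affinity count per state and treatment
   (fraction of predictive affinity above the control reference × expected
   total count).

A first-class synthetic-data module generates seeded, ground-truth-annotated
imaging volumes (cDC1 filament networks, clustered vs dispersed T cells with
phenotype-dependent marker intensities) and multi-mouse cytometry event
tables with exactly the hierarchical structure the models assume — so every
stage is exercisable and testable without any download.

## The statistics at the core

Per cell *i* the imputed affinity index is `a_i = tetramer_i / CD3_i`, and
`z_i = (log a_i − mean_ref) / sd_ref` with the reference pool being
control-IgG SLAMF6+ T_SL events of the same experimental cohort. The
affinity model is

```
z_i = x(state_i, treatment_i)' β + u0_m(i) + u1_m(i),state_i + ε_i,
ε ~ N(0, σ²),  u0_j ~ N(0, τ0²),  u1_j,s ~ N(0, τs²)
```

with conjugate priors (β ~ N(0, 5²I); inverse-gamma(2, 1) on σ², τ²). The
count model is identical with standardized log counts per (mouse, state) as
the response. Population-level predictions drop the `u` terms; the expected
high-affinity count for a (state, treatment) cell is
`P(ŷ > 0) × E[count]`, both per posterior draw.

The spatial covariate "cDC1 density" of a cell is the XCR1 channel filtered
per z-slice with a unit-sum 2D Gaussian (σ = 3.6 µm by default), averaged
under the cell's nuclear mask; the `cDC1-density^high` gate thresholds
max-normalised densities at mean + 1 population SD.

## Worked example

```python
import tslniche as t
from tslniche import cell_quant, spatial, histocytometry

p = t.SynthImageParams(volume_shape=(16, 128, 128), n_dc=3, n_tcells=30,
                       nuclear_radius_range=(1.5, 2.5), cluster_radius=8.0,
                       noise_sd=0.0, seed=11)
stack, nuc, truth = t.simulate_ln_image(p)
_, mem = cell_quant.expand_labels_membrane(nuc, 6)      # radius-6 dilation
cells = cell_quant.quantify_cells(stack, nuc, mem)
dens = spatial.dc_density(stack, "XCR1", nuc, sigma=3.6)
flags, thr, norm = histocytometry.dc_high_gate(dens)
```

prints, via the obvious f-strings:

```
cells quantified: 30
cDC1-density^high threshold (mean + 1 s.d.): 0.506
cDC1-density^high cells: 3/30
mean density clustered: 25.52  dispersed: 8.74
```

i.e. 30 T cells were quantified; the density gate sits at 0.506 on the
max-normalised scale and captures 3 cells; cells the generator placed inside
dendritic niches register about three times the cDC1 density of dispersed
cells — the spatial signal the niche analysis is built to detect.

The same pipeline is available from the shell:

```
tslniche simulate-image --config cfg.yaml --seed 4 --out sim/
tslniche quantify --stack sim/stack.tiff --labels sim/labels.tiff --radius 6 --out cells.csv
tslniche affinity --events events.csv --reference IgG:SLAMF6posTSL --out affinity.csv
tslniche model --events affinity.csv --counts counts.csv --seed 7 --out model/
```

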