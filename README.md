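# jointseg

Joint cell segmentation and cell-type annotation for hybridization-based
spatial transcriptomics (MERFISH, osmFISH and similar spot-table data).

## The problem

Imaging-based spatial transcriptomics delivers a 3D point cloud of decoded
mRNA molecules plus DAPI-stained nuclei, but no cell boundaries. Assigning
each transcript to a cell is the step every downstream analysis depends on,
and purely geometric approaches (growing regions from nuclei by distance or
local transcript density) ignore a strong source of information: cells of
different types express different genes, so the *composition* of local
transcript density says which cell a boundary pixel belongs to.

`jointseg` segments and annotates jointly by expectation-maximization:

1. The volume is divided into a regular pixel grid (edge 2 μm on empirical
   data, 1 μm in simulations). For every gene *g* and pixel, the local
   density is estimated by K-nearest neighbours:
   *density = K / ((4/3)·π·r³)* with *r* the distance to the K-th nearest
   spot of *g* (K = 5), giving the pixel expression matrix **E**ₚ (nₚ × m).
2. Cells are initialized by watershed on the distance transform of the
   nuclei, capped at *d* = 2 μm, and typed once with a cell-level classifier
   *f*_θ trained on a scRNA-seq reference taxonomy (harmonized by two-pass
   z-scoring: per cell across genes, then per gene across cells).
3. **M-step:** a pixel-level classifier *g*_ϕ (input *m* marker densities,
   hidden widths 2m–4m–8m, tanh + batch norm, softmax over the k reference
   types) is trained on 10% of the assigned pixels, labelled by their cell's
   type; later rounds warm-start from the previous parameters.
4. **E-step:** border pixels (≥5 of 26 neighbours from a different cell, ≥2
   from their own, at an interface between different types or cell and
   background) get probabilities *q* = *g*_ϕ(**E**ₚ), rescaled by distance to
   candidate nuclei — *q′ᵢ* = 10 if *rᵢ* < *d*, else *qᵢ*·5d/(2(rᵢ−d)) capped
   at 10, so *q* halves at *rᵢ* = 6d — masked to the types of adjacent cells,
   floored, renormalized, annealed (max entry × (1 + 0.05·iteration)) and
   sampled from the resulting multinomial. Interfaces between same-type
   cells stay as watershed drew them; pixels with no admissible type become
   background.
5. Steps 3–4 alternate on a fixed schedule (6 × 10 on empirical data,
   5 × 5 in simulations), then each spot is assigned to the cell owning its
   pixel, producing a cell × gene count matrix over the full panel.

The package also ships the pieces needed to evaluate and use the result: a
ground-truth tissue simulator, a compactness-weighted density-watershed
baseline, a taxonomy-aware accuracy metric (misassignments between touching
cells of the same (sub)type group are not penalized, swept over dendrogram
cut heights 0–0.8), a neighbour-composition colocalization permutation test,
and a within-type spatial differential-expression (spDEG) permutation test.

## Worked example

```python
from jointseg import (
    SimulationParams, make_synthetic_taxonomy, simulate_tissue,
    JointSegmentationModel, assignment_accuracy,
)
from jointseg.model import ReassignmentParams

# six well-separated cell types over a 20-gene panel
taxonomy = make_synthetic_taxonomy(n_types=6, n_genes=20, seed=1)
tissue = simulate_tissue(SimulationParams(extent=(60, 60, 20), seed=11), taxonomy)

model = JointSegmentationModel(
    tissue.spots, tissue.nuclei, taxonomy, pixel_size=1.0,
    params=ReassignmentParams.for_simulation(seed=11),
)
result = model.fit(seed=11)
print(result.summary())

baseline = model.fit_watershed()
em = assignment_accuracy(result, tissue, taxonomy)
ws = assignment_accuracy(baseline, tissue, taxonomy)
print(f"EM accuracy (finest granularity):        {em.mean_accuracy[0]:.3f}")
print(f"Watershed accuracy (finest granularity): {ws.mean_accuracy[0]:.3f}")
```

prints

```
Joint segmentation results
========================================
method:            em
grid shape:        (62, 62, 22) @ 1.0 um
cells:             310
types present:     6
spots assigned:    188044 / 188174
EM iterations:     25 (total flips 224576)
mean max P(type):  0.949 -> 0.883 -> 0.898 -> 0.909 -> 0.913

EM accuracy (finest granularity):        0.859
Watershed accuracy (finest granularity): 0.759
```

The simulated tissue holds 310 irregular cells and ~188k transcripts. The EM
model assigns 99.9% of transcripts to cells and places 85.9% of them in the
correct cell (or a touching cell of the same type) at the finest type
resolution, versus 75.9% for the density watershed; `mean max P(type)` shows
the pixel classifier's confidence rising over the five training rounds.
`result.cell_counts`, `result.cell_types` and `result.cell_centroids()` feed
directly into `colocalization_test` and `spdeg_test`.

A thin CLI wraps the same functionality:
`jointseg simulate|segment|evaluate|coloc|spdeg --help`.

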