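# astroquant

Quantification toolkit for cell-biology studies of astrocyte senescence
and mitochondrial dysfunction. It packages, as tested library code, the
image- and assay-analysis steps that usually live in ad-hoc FIJI macros
and spreadsheets:

* **Mitochondrial network morphometry** — CLAHE enhancement, Hessian
  tubeness (ridge) filtering, skeletonization, per-cell counts/areas/
  densities, and the **perinuclear distribution ratio**: the fraction of
  the network inside a zone grown from the nucleus to 1.2× its area,
  divided by that zone's share of the cell area (1 = uniform, >1 =
  perinuclear clustering).
* **Senescent-cell counting** — nuclei counted in DAPI, H2A.X⁺ nuclei
  called by per-nucleus mean intensity, each positive nucleus dilated by
  1.89 µm into a halo, and GFAP signal in the halo used to call which
  senescent cells are astrocytes.
* **Colocalization** — per-cell intersection area of two binarized
  channels (e.g. TOMM20 × LC3B) plus line-profile extraction.
* **Extracellular flux** — Mito Stress Test decomposition of OCR/ECAR
  traces (basal, ATP-linked, proton leak, maximal, spare, non-mito,
  coupling efficiency, ECAR rise after oligomycin) with per-cell
  normalization.
* **Expression statistics** — the gene set score
  (c_ij = e_ij − mean_j e_ij, S_j = mean_i c_ij), 2^−ΔΔCt relative
  quantification against a housekeeping gene, fold/percent-change
  helpers, and a Shapiro-Wilk-gated comparison ladder (t-test / ANOVA +
  Tukey vs Mann-Whitney / Kruskal-Wallis + Dunn, Wilcoxon for paired
  non-normal data) with significance stars.
* **Synthetic fixtures** — generators for images, flux traces and
  expression matrices with machine-readable ground truth, so every stage
  is testable without downloading data.

See `docs/methods.md` for the full description of each procedure and its
parameters.

## Worked example

Generate a noisy synthetic tissue field (50 cells, 20 % H2A.X⁺ nuclei,
80 % of the positives wrapped in GFAP⁺ cytoplasm), segment the nuclei and
run the senescence counter:

```python
from astroquant import imaging, senescence, synthetic

spec = synthetic.SyntheticImageSpec(
    image_size_px=(512, 512), pixel_size_um=0.5, n_cells=50,
    nucleus_radius_um=(3.0, 4.5), cell_radius_um=(7.0, 11.0),
    mito_per_cell=0, frac_marker_pos_nuclei=0.2, frac_gfap_among_pos=0.8,
    noise_sd=10.0, seed=1,
)
stack, _, cells, truth = synthetic.generate_image(spec)
proj = imaging.max_project(stack)
nuclei = imaging.segment_nuclei(imaging.split_channel(proj, "DAPI"))
res = senescence.count_senescent(
    proj.plane("H2AX"), proj.plane("GFAP"), nuclei, spec.pixel_size_um)
print(f"{res.n_cells} nuclei, {res.n_pos} H2A.X+ ({res.pct_pos:.1f}%), "
      f"{res.n_pos_astro} astrocytic ({res.pct_pos_astro:.1f}% of positives)")
```

prints

```
50 nuclei, 10 H2A.X+ (20.0%), 8 astrocytic (80.0% of positives)
```

— the counter recovered both generator fractions exactly despite the 10 %
signal noise. Mitochondrial morphometry runs the same way:

```python
from astroquant import mito

spec = synthetic.SyntheticImageSpec(n_cells=3, mito_per_cell=8,
                                    image_size_px=(640, 640), seed=7)
stack, nuclei, cells, truth = synthetic.generate_image(spec)
print(mito.analyze_mito(stack, nuclei, cells)
      [["cell_id", "n_mitochondria", "mito_area_um2", "perinuclear_ratio"]]
      .round(3).to_string(index=False))
```

```
 cell_id  n_mitochondria  mito_area_um2  perinuclear_ratio
       1               8          13.40              1.357
       2               8          14.08              1.100
       3               8          15.76              1.244
```

Each cell's 8 planted filaments are recovered, and the perinuclear ratios
sit near 1 because placement was uniform. Group summaries use the
expression helpers, e.g. `fold_change(78.77, 29.28, 2)` → `2.69`, the
ratio of two group means rounded half-up to two decimals.

A `astroquant` console script exposes the same pipelines
(`synth`, `mito`, `coloc`, `senescence`, `flux`, `score`, `ddct`,
`stats`); run `astroquant --help`.

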