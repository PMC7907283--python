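# mifscape

Spatial immune profiling of multiplex-immunofluorescence (mIF)
cell-segmentation tables: co-expression phenotyping, compartmentalized cell
densities, malignant-to-immune proximity analysis, and nearest-neighbour
G-function classification of mixed vs unmixed immune landscapes.

The pipeline starts from cell-level tables (one row per nucleated cell with
X/Y coordinates in µm, marker positivity flags, ROI and compartment labels)
such as those exported by image-analysis systems, and comprises:

- **datamodel / io** — canonical CSV cell-table format (8-marker panel:
  panCK, PD-L1, PD-1, CD3, CD8, Foxp3, KI67, CD68), per-marker event
  tables, pixel↔µm conversion (0.5 µm/pixel), ROI geometry (931 × 698 µm
  default) and deterministic output writing.
- **qc** — per-ROI malignant-content check (≥ 85 % panCK+ cells in the
  epithelial compartment by default).
- **phenotyping** — coordinate-based merging of per-marker calls onto the
  DAPI spine (nearest match within a tolerance, default 0.5 µm), a 26-rule
  nested co-expression phenotype registry across the panCK / CD3 / CD68
  lineages, and case-level PD-L1 status (> 1 % of malignant cells).
- **density** — cells/mm² per (case, phenotype, compartment) with cohort
  median/min/max, Wilcoxon rank-sum compartment comparisons, and
  TMA staining-consistency QC (Spearman across staining runs, Bonferroni).
- **proximity** — median nearest-neighbour distances from malignant-cell
  strata (panCK+, panCK+PD-L1−, panCK+PD-L1+) to each immune phenotype,
  the cohort's overall median radius, close/far labels, and radius-sweep
  counts.
- **gfunction** — empirical cross-type G function vs the theoretical
  Poisson curve `1 − exp(−λπr²)` at the observed intensity; an ROI is
  *mixed* when the deviation (percentage points of G) stays within
  [−10, +10] over 0–200 µm, *unmixed* when it exceeds +10, otherwise
  *indeterminate*; case labels by majority vote over ROIs.
- **simulate** — synthetic tumor-microenvironment generator (tumor-cell
  nests, tunable immune mixing, marker co-expression frequencies, replicate
  staining runs) with ground-truth sidecars, used by the test suite in
  place of the study's non-deposited patient data.

## CLI

```sh
mifscape simulate --preset mixed_demo --seed 7 --out-dir out/sim
mifscape phenotype out/sim/cells.csv --out-dir out/ph
mifscape density   out/sim/cells.csv --out-dir out/dens
mifscape spatial   out/sim/cells.csv --out-dir out/prox
mifscape patterns  out/sim/cells.csv --out-dir out/pat
mifscape qc        out/sim/cells.csv --out-dir out/qc
mifscape run --config run.yaml --seed 7 --out-dir out/full
```

A run config is YAML with optional blocks `panel`, `input`
(`cell_table:` path or `preset:` `mixed_demo`/`unmixed_demo`),
`simulation` (preset overrides), `analysis` and `output`.

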