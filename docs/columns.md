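# Single-cell table column dictionary

All pipeline stages operate on flat delimited-text tables (CSV), one row
per segmented cell.  Stages append columns and never reorder rows.

## Identifier and geometry columns

| column             | type   | meaning                                                        |
|--------------------|--------|----------------------------------------------------------------|
| `cell_id`          | string | unique cell identifier (`<core>_c<index>` for synthetic data)  |
| `core_id`          | string | TMA core identifier                                            |
| `patient_id`       | string | patient / case identifier (one core per case on this TMA)      |
| `cancer_group`     | string | organ-system cancer group of the core (annotation, optional)   |
| `x_um`, `y_um`     | float  | cell centroid in µm, origin at the core bounding-box corner    |
| `nucleus_size_um2` | float  | nucleus area in µm² (QC criterion)                             |

## Intensity columns (wide, prefixed)

| prefix   | produced by                | meaning                                            |
|----------|----------------------------|----------------------------------------------------|
| `af_<c>` | segmentation / simulator   | per-cell autofluorescence estimate for channel `c` |
| `raw_<m>`| segmentation / simulator   | mean raw intensity of marker `m`                   |
| `corr_<m>`| `subtract_autofluorescence`| `max(0, raw_<m> − af_<channel(m)>)`               |
| `z_<m>`  | `zscore_normalize`         | z-score of `corr_<m>` within its group             |

The marker→channel map ships with the panel config
(`cycifspatial/data/default_panel.yaml`); channels default to
`ch488, ch555, ch647, ch750` assigned cyclically.

## Phenotype column

`phenotype` — label assigned by `assign_phenotypes`; `unassigned` when no
gate matches.

## Ground-truth sidecar (synthetic data only)

`truth_cells.csv`: `cell_id`, `core_id`, `true_phenotype`, `in_niche`
(within the niche radius of a planted reference cell), `is_reference`
(a planted reference cell), `qc_outlier` (given corrupted nucleus size or
autofluorescence).

`truth_cores.csv`: `core_id`, `patient_id`, `true_tme_class` (empty unless
the config pins per-core classes), `cancer_group`.

## Core summary table

`compute_densities` → one row per core: `core_id`, `patient_id`,
`cancer_group`, `core_area_mm2`, then `count_<p>` and `density_<p>`
(cells/mm²) per phenotype; `add_infiltration` adds boolean
`infiltrated_<p>`; `classify_cores` adds `immune_frac`, `stromal_frac`,
`tme_class`.

## Spatial outputs

* distances table: `cell_id`, `core_id`, `phenotype`,
  `nearest_reference_um` (NaN when undefined).
* zones table: adds `zone` ∈ {proximal, intermediate, distal, beyond,
  undefined}.
* annulus tables: per-core and pooled counts per half-open annulus
  `[e_i, e_{i+1})` plus a `beyond` remainder.
* zone comparison: `cell_type`, `marker`, `n_patients_paired`,
  `prox_median`, `dist_median`, `log_fc`, `direction`, `n_zero_dropped`,
  `W`, `p_value`, `q_value`, `stars`, `evaluable`.
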