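# Methods

This note records the models, conventions and numerical choices behind
`cycifspatial`, in the spirit of a statistical software methods appendix.
Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## Pipeline overview

The unit of data is the segmented single-cell feature table of a cyclic
immunofluorescence TMA: per cell, a core/patient identifier, centroid
coordinates in µm, nucleus area, per-marker mean raw intensities, and
per-channel autofluorescence estimates.  The pipeline applies, in order:

1. **QC** — retain cells with nucleus area inside an inclusive interval
   (default 10–1000 µm²) and, per core and channel, autofluorescence at or
   below the configured empirical quantile (default 0.99).
2. **Autofluorescence subtraction** — `corr = max(0, raw − af_channel)`
   per cell and marker.  Negative corrected values are clamped to zero:
   intensities are physical quantities and downstream fold changes require
   non-negative values.
3. **Z-score normalization** — per marker within a group (default: each
   core separately, matching the batch structure of cyclic imaging;
   `global` is available for sensitivity analysis),
   `z = (corr − mean) / sd` with the *population* SD (divide by n).  The
   population convention is arbitrary but fixed and documented; zero-variance
   and singleton groups get z = 0.
4. **Gating** — a cell is positive for marker m iff `z_m ≥ 0.5`; in the
   default single-threshold mode, negative means not positive, so every
   cell is classifiable.  A strict two-threshold mode (negative iff
   `z ≤ −0.5`, dead-zone cells unassigned) exists for sensitivity
   analysis.  Rules are evaluated most-specific-first by explicit priority;
   first match wins; non-matching cells are `unassigned`.
5. **Densities** — exact per-core counts divided by core area.  Area
   defaults to the nominal 1-mm disc (π/4 mm² ≈ 0.7854); a convex-hull
   estimate is available for partially filled cores.  Infiltration is
   presence/absence: count ≥ 1 by default.
6. **TME classes** — see below.
7. **Spatial statistics** — see below.

## Phenotype panel

Only the three CXCL13+ CD4 T-cell gates (Tph, Tfh, and the CCR2-negative
Tph-like state) are fixed by their published marker definitions.  All other
gates in the shipped panel (Th1, Th17, CD8 T, B-cell subsets including DN2
and unswitched memory, M1/M2 macrophages, cancer cells) are *surrogate*
definitions expressed over the same 14-marker panel; real analyses should
edit `data/default_panel.yaml` to use dedicated lineage markers (CD20,
CD68/CD163, panCK, …) where available.  The panel deliberately contains no
stromal gate; see the TME fallback below.

## Synthetic cohort model

The generator exists so that every downstream stage has a known answer.

* **Geometry.**  Each core is a disc of diameter 1 mm; coordinates are in
  µm with origin at the bounding-box corner.  Background cells follow a
  homogeneous Poisson process (default 2000 cells/mm², ~1570 cells per
  core — a typical density for solid-tumour sections) with labels drawn
  from configured phenotype proportions.
* **Niches.**  A Thomas-like parent–offspring construction: a fixed number
  of reference cells are placed uniformly; for each enriched phenotype with
  factor e > 1, offspring counts are Poisson with mean
  `(e − 1) × background expectation of that phenotype on the parent's
  niche area inside the core`, and offspring are uniform on that clipped
  area.  Total in-niche density is then exactly e × background density, so
  the configured enrichment *is* the realized density ratio (verified to
  ±0.4 over 100-core pilots).  The expected count scales with the
  circle–circle intersection area of niche and core so that edge-adjacent
  parents do not concentrate offspring.  Factors e < 1 thin the background
  inside niches instead.
* **Intensities.**  For marker m, a cell draws
  `lognormal(mu_pos, σ)` if its true phenotype's gate lists m positive,
  else `lognormal(mu_neg, σ)`; an additive per-channel lognormal
  autofluorescence draw is added to form the raw intensity and recorded as
  the cell's AF estimate.  Defaults: median 300 vs 20 intensity units
  (15× positive/negative ratio), σ = 0.25 on the log scale, AF median 8 —
  a clean but realistic immunofluorescence panel.  We define the
  **separation** of a marker model as
  `s = |mu_pos − mu_neg| / sqrt((σ_pos² + σ_neg²)/2)` on the log scale;
  the defaults give s ≈ 10.8.  Gating recovery degrades gracefully as s
  shrinks and single-threshold gating cannot reach high accuracy near
  s = 2 (the components overlap too much on the z scale); the shipped
  defaults are comfortably inside the well-separated regime, and the
  recovery tests state the regime they certify.
* **QC contamination.**  A configured fraction of cells receives either an
  out-of-range nucleus area or a 50× inflated autofluorescence on one
  channel, flagged in the ground truth.
* **TME scenarios.**  A config may pin per-core classes; each class maps to
  expected (immune, cancer, other) fractions — IE (0.45, 0.45, 0.10),
  IE/F (0.40, 0.20, 0.40), F (0.08, 0.40, 0.52), D (0.08, 0.85, 0.07) —
  chosen to separate each fraction from the 0.2 cuts by at least 2×.
  "Other" cells are marker-negative and represent the stromal compartment.
* **Reproducibility.**  Core i uses
  `numpy.random.SeedSequence([master_seed, i])`, so cores are independent
  and a cohort is byte-identical for a given config and seed, regardless
  of generation order.
* **What the generator does not emulate.**  No pixel-level imaging, no
  staining/quenching cycle artefacts, no registration or segmentation
  error, no spatial correlation beyond the planted niches, no per-patient
  biological heterogeneity in intensity distributions.  Passing tests
  certify the *algorithms* under a known data-generating process, not
  performance on any real cohort.

## Spatial statistics

* **Nearest-reference distance.**  Per core, the Euclidean distance of
  each cell to the nearest reference-phenotype cell (k-d tree; verified
  against an exhaustive all-pairs oracle to 1e-9).  Reference cells get
  the distance to their nearest *other* reference; a lone reference, or
  every cell in a core without references, is flagged undefined (NaN)
  rather than erroring.
* **Annuli.**  Half-open bins `[e_i, e_{i+1})` with default edges 0, 25,
  50, 75, 100 µm; cells past the last edge land in a `beyond` remainder so
  totals are conserved exactly.  Counts are reported raw (as cell counts
  per interval); an optional Monte-Carlo estimate of each nearest-distance
  band's area within the core supports density readouts — the band of a
  union of annuli clipped by the core has no closed form, so uniform
  sampling in the disc is used (seeded, 20k points by default).
* **Zones.**  Proximal `[0, 50)` µm, distal `[151, 200)` µm,
  intermediate between them, `beyond` past 200 µm.  Half-open intervals
  partition distances without double counting; the windows are
  configuration.
* **Paired zone comparison.**  Per (cell type, marker): for each patient
  with ≥ 1 cell of the type in both zones, the per-zone median
  AF-corrected intensity; the paired per-patient medians enter a one-sided
  Wilcoxon signed-rank test, and
  `log_fc = median_patients log2((prox + ε)/(dist + ε))` with
  `ε = 1e-6 × global marker mean` keeps fold changes finite at zero.
  Corrected intensities, not z-scores, are the default value scale because
  fold changes of signed z-scores are ill-defined (z-scores remain
  available).  Benjamini–Hochberg correction runs across the whole
  (cell type × marker) grid; entries with fewer than 5 paired patients
  report the fold change but no test.

### Direction of the one-sided test

The default alternative is `greater` (proximal > distal): the scientific
hypothesis embedded in the analysis is that immune activity concentrates
*near* the reference population, and an a-priori direction keeps the test
calibrated — the per-entry null rejection rate at α = 0.05 is ≈ 0.05
(measured 0.03–0.05 over 1000 null simulations).  A data-driven direction
(`auto`, testing the side favoured by the observed median difference, with
the choice recorded per entry) is available but is anti-conservative: it
doubles the null rejection rate to ≈ 0.10 and should be paired with a
halved α or a two-sided reading.  `less` and `two-sided` are also exposed.
Zero differences are dropped before ranking (classical convention) and
their count reported.

## Test statistics

* **Mann–Whitney U** (density comparisons): exact enumeration when both
  groups have ≤ 8 observations and the pooled sample is tie-free;
  otherwise the normal approximation with tie and continuity corrections.
  Verified against full enumeration of all group assignments.
* **Wilcoxon signed-rank**: exact null distribution for ≤ 25 tie-free
  non-zero differences, normal approximation with continuity correction
  otherwise.  Verified against enumeration of all 2^n sign assignments for
  n ≤ 12.
* **BH adjustment**: statsmodels step-up implementation, verified exactly
  against the literal definition `q_(i) = min_{j≥i} m·p_(j)/j` capped at 1.
* **Stars**: `*` q < 0.05, `**` q < 0.01, `***` q < 0.001, `****`
  q < 0.0001 on the FDR-adjusted values.

## TME classification

A transparent two-axis threshold rule: with immune fraction i and stromal
fraction s of a core's cells, IE iff i ≥ 0.2 and s < 0.2; IE/F iff both
≥ 0.2; F iff i < 0.2 and s ≥ 0.2; D otherwise; empty cores are D with a
warning.  This is a deliberate surrogate for transcriptomics-based TME
classifiers — reproducible and fully configurable, but not a reimplementation
of any published classifier, and its labels should not be presented as such.
Because the default panel has no stromal gate, the stromal fraction falls
back to `1 − immune − cancer` fraction (cells matching no immune or tumour
gate).  The rule recovers generator-assigned classes perfectly when applied
to true phenotype fractions.

## Known limitations

* **Prevalence-dependent gating.**  Z-scores are computed within cores, so
  a marker's positive fraction shifts the group mean and SD.  When one
  population dominates a core (e.g. a tumour-rich immune-desert core at
  ~85% cancer cells), its defining markers' z-scores compress below the
  0.5 cut, cells fall to `unassigned`, and — via the stromal fallback —
  desert cores can read as fibrotic.  At the default cohort composition
  (no marker above ~31% prevalence) gating recovery exceeds 98%, but
  extreme compositions need either global normalization, panel-specific
  thresholds, or explicit stromal markers.
* **Quantile QC is adaptive, not absolute.**  The autofluorescence
  criterion removes the top tail per core; it is not idempotent and cannot
  catch contamination heavier than its tail (e.g. a 0.99 quantile cut
  cannot remove 10% contaminated cells).  Absolute thresholds are
  available by configuration.
* **Annulus counts ignore overlap between reference neighbourhoods** in
  their raw form (by design, counts are binned by *nearest* reference);
  the Monte-Carlo band areas are the supported route to densities.
* **One core per patient.**  The TMA design makes core and patient
  interchangeable here; multi-core designs would need a patient-level
  aggregation flag in the density comparisons.

## Problem sizes

The shipped verification suite uses: 10-core (~15k cell) cohorts for
normalization and gating recovery; 1000 null and 500 shifted 20-patient
cohorts for calibration and power of the paired zone test; 100–200 cores
for niche enrichment; exhaustive oracles at n ≤ 12 (signed-rank),
group sizes ≤ 8 (Mann–Whitney), and 1050 cells / 50 references (nearest
distances).  `scripts/acceptance.py` uses slightly smaller simulation
counts (500 null / 200 shifted cohorts, 100-core niche runs) chosen to
keep a full from-scratch rerun under a minute while leaving Monte-Carlo
error well inside the margins of the properties being checked.
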