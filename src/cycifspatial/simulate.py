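"""Synthetic TMA cohort generator with known ground truth.

Emulates segmented single-cell feature tables from a tissue microarray imaged
by cyclic immunofluorescence: each core is a 1-mm-diameter disc populated by
a homogeneous Poisson background of phenotype-labelled cells, optionally with
clustered immune niches seeded around uniformly placed reference cells
(a parent–offspring, Thomas-like construction).  Marker intensities are
lognormal with separate positive/negative components chosen per cell from
its true phenotype's gate, plus an additive per-channel autofluorescence
draw, so the downstream autofluorescence subtraction, z-scoring, and gating
stages all have real work to do and a known answer.

Reproducibility: every random draw comes from a per-core generator seeded by
the composite entropy ``(master_seed, core_index)`` via
:class:`numpy.random.SeedSequence`, so cores are independent, parallel-safe,
and byte-identical across runs for the same config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import panels
from .phenotyping import PhenotypeRule
from .schema import NUCLEUS_COLUMN, UNASSIGNED, af_col, raw_col

__all__ = [
    "MarkerIntensityModel",
    "ChannelAFModel",
    "NicheSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_core",
    "generate_cohort",
    "generate_paired_zone_cohort",
    "config_from_yaml",
    "config_to_yaml",
    "TME_CLASS_MIXES",
]


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class MarkerIntensityModel:
    """Lognormal positive/negative intensity components (log scale)."""

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float

    def __post_init__(self) -> None:
        if self.sigma_pos <= 0 or self.sigma_neg <= 0:
            raise ConfigurationError("intensity sigmas must be strictly positive")

    @property
    def separation(self) -> float:
        """Standardized positive/negative gap, |mu_pos − mu_neg| / pooled SD."""
        pooled = math.sqrt((self.sigma_pos**2 + self.sigma_neg**2) / 2.0)
        return abs(self.mu_pos - self.mu_neg) / pooled


@dataclass(frozen=True)
class ChannelAFModel:
    """Lognormal per-channel autofluorescence (log scale)."""

    mu_af: float
    sigma_af: float

    def __post_init__(self) -> None:
        if self.sigma_af <= 0:
            raise ConfigurationError("autofluorescence sigma must be strictly positive")


@dataclass(frozen=True)
class NicheSpec:
    """Clustered-niche specification.

    ``n_reference_cells`` reference cells are placed uniformly in the core;
    for each phenotype in ``enrichment`` with factor e, offspring are added
    around each reference so that the total density inside the niche disc of
    radius ``niche_radius_um`` is e × the background density of that
    phenotype (factors below 1 thin the background inside niches instead).
    """

    reference_phenotype: str
    n_reference_cells: int
    niche_radius_um: float
    enrichment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.niche_radius_um <= 0:
            raise ConfigurationError("niche_radius_um must be strictly positive")
        if self.n_reference_cells < 0:
            raise ConfigurationError("n_reference_cells must be non-negative")
        for p, e in self.enrichment.items():
            if e < 0:
                raise ConfigurationError(f"enrichment factor for {p!r} must be >= 0")


# Expected (immune, cancer) cell fractions per tumour-microenvironment class,
# used when a config pins per-core classes; the remainder is emitted as
# marker-negative (stromal/other) cells.
TME_CLASS_MIXES: dict[str, tuple[float, float]] = {
    "IE": (0.45, 0.45),
    "IE/F": (0.40, 0.20),
    "F": (0.08, 0.40),
    "D": (0.08, 0.85),
}

#: Default background phenotype composition (fractions of all cells).
DEFAULT_PROPORTIONS: dict[str, float] = {
    "Tph": 0.02,
    "Tfh": 0.01,
    "Tph_like": 0.04,
    "Th1": 0.03,
    "Th17": 0.02,
    "CD4_T": 0.08,
    "CD8_T": 0.10,
    "B_naive": 0.06,
    "B_mem_unswitched": 0.03,
    "B_DN2": 0.02,
    "M1_mac": 0.04,
    "M2_mac": 0.04,
    "Cancer": 0.31,
    UNASSIGNED: 0.20,
}


def default_intensity_model(markers: list[str] | None = None) -> dict[str, MarkerIntensityModel]:
    """15× positive/negative median ratio, CV ≈ 25% — a clean, realistic panel."""
    markers = markers if markers is not None else panels.default_markers()
    model = MarkerIntensityModel(
        mu_pos=math.log(300.0), sigma_pos=0.25, mu_neg=math.log(20.0), sigma_neg=0.25
    )
    return {m: model for m in markers}


def default_af_model(channels: list[str] | None = None) -> dict[str, ChannelAFModel]:
    channels = channels if channels is not None else panels.default_channels()
    return {c: ChannelAFModel(mu_af=math.log(8.0), sigma_af=0.3) for c in channels}


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic TMA cohort."""

    n_cores: int = 10
    core_diameter_mm: float = 1.0
    background_density: float = 2000.0  # cells per mm²
    phenotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    niche_spec: NicheSpec | None = None
    intensity_model: dict[str, MarkerIntensityModel] = field(
        default_factory=default_intensity_model
    )
    autofluorescence_model: dict[str, ChannelAFModel] = field(default_factory=default_af_model)
    channel_map: dict[str, str] = field(default_factory=panels.default_channel_map)
    rules: list[PhenotypeRule] = field(default_factory=panels.default_rules)
    qc_contamination: float = 0.0
    core_classes: list[str] | None = None  # per-core TME class (cycled over cores)
    cancer_groups: list[str] | None = None  # per-core group labels (cycled)
    nucleus_mu_um2: float = 50.0
    nucleus_sigma_log: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cores < 1:
            raise ConfigurationError("n_cores must be >= 1")
        if self.core_diameter_mm <= 0:
            raise ConfigurationError("core_diameter_mm must be strictly positive")
        if self.background_density < 0:
            raise ConfigurationError("background_density must be non-negative")
        if not 0.0 <= self.qc_contamination < 1.0:
            raise ConfigurationError("qc_contamination must lie in [0, 1)")
        total = sum(self.phenotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype_proportions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.phenotype_proportions.values()):
            raise ConfigurationError("phenotype_proportions must be non-negative")
        if self.niche_spec is not None:
            unknown = set(self.niche_spec.enrichment) - set(self.phenotype_proportions)
            if unknown:
                raise ConfigurationError(
                    f"enrichment phenotypes not in proportions: {sorted(unknown)}"
                )
        known = {r.name for r in self.rules} | {UNASSIGNED}
        unknown = set(self.phenotype_proportions) - known
        if unknown:
            raise ConfigurationError(f"phenotypes without a gating rule: {sorted(unknown)}")
        if self.core_classes is not None:
            bad = set(self.core_classes) - set(TME_CLASS_MIXES)
            if bad:
                raise ConfigurationError(f"unknown TME classes: {sorted(bad)}")
        markers = sorted({m for r in self.rules for m in r.markers})
        missing = [m for m in markers if m not in self.intensity_model]
        if missing:
            raise ConfigurationError(f"markers without intensity model: {missing}")
        missing = [m for m in markers if m not in self.channel_map]
        if missing:
            raise ConfigurationError(f"markers without channel mapping: {missing}")
        for m in markers:
            ch = self.channel_map[m]
            if ch not in self.autofluorescence_model:
                raise ConfigurationError(f"channel {ch!r} has no autofluorescence model")

    # -- derived geometry ---------------------------------------------------
    @property
    def radius_um(self) -> float:
        return self.core_diameter_mm * 1000.0 / 2.0

    @property
    def core_area_mm2(self) -> float:
        return math.pi * (self.core_diameter_mm / 2.0) ** 2

    @property
    def markers(self) -> list[str]:
        return sorted({m for r in self.rules for m in r.markers})

    @property
    def channels(self) -> list[str]:
        return sorted({self.channel_map[m] for m in self.markers})

    def min_separation(self) -> float:
        """Smallest standardized positive/negative gap over markers."""
        return min(self.intensity_model[m].separation for m in self.markers)


@dataclass
class GroundTruth:
    """Generator-side truth: per-cell labels and per-core class annotations.

    ``cells`` has columns ``cell_id, core_id, true_phenotype, in_niche,
    is_reference, qc_outlier``; ``cores`` has ``core_id, patient_id, true_tme_class,
    cancer_group`` (``true_tme_class`` is NA when no class scenario is set).
    """

    cells: pd.DataFrame
    cores: pd.DataFrame


def _core_proportions(config: SyntheticConfig, core_index: int) -> dict[str, float]:
    """Per-core phenotype mix, reweighted to the core's TME class if pinned."""
    props = dict(config.phenotype_proportions)
    if config.core_classes is None:
        return props
    cls = config.core_classes[core_index % len(config.core_classes)]
    immune_target, cancer_target = TME_CLASS_MIXES[cls]
    other_target = 1.0 - immune_target - cancer_target
    groups = {
        "immune": [p for p in props if p in panels.IMMUNE_PHENOTYPES],
        "cancer": [p for p in props if p in panels.CANCER_PHENOTYPES],
        "other": [
            p
            for p in props
            if p not in panels.IMMUNE_PHENOTYPES and p not in panels.CANCER_PHENOTYPES
        ],
    }
    targets = {"immune": immune_target, "cancer": cancer_target, "other": other_target}
    out: dict[str, float] = {}
    for g, members in groups.items():
        base = sum(props[p] for p in members)
        if targets[g] > 0 and not members:
            raise ConfigurationError(f"TME class {cls!r} needs {g} phenotypes in proportions")
        for p in members:
            share = props[p] / base if base > 0 else 1.0 / len(members)
            out[p] = targets[g] * share
    return out


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _clipped_niche_area_um2(parents: np.ndarray, niche_radius: float, core_radius: float) -> np.ndarray:
    """Area of each parent's niche disc intersected with the core disc (µm²).

    Standard circle-circle lens formula; parents are assumed inside the core,
    so the intersection is the full niche disc whenever the niche does not
    reach the boundary.
    """
    rho = np.sqrt(np.einsum("ij,ij->i", parents, parents))
    r, R = niche_radius, core_radius
    full = np.pi * r**2
    area = np.full(len(parents), full)
    clip = rho + r > R
    if clip.any():
        d = np.clip(rho[clip], 1e-9, None)
        a1 = r**2 * np.arccos(np.clip((d**2 + r**2 - R**2) / (2 * d * r), -1, 1))
        a2 = R**2 * np.arccos(np.clip((d**2 + R**2 - r**2) / (2 * d * R), -1, 1))
        s = (-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R)
        area[clip] = a1 + a2 - 0.5 * np.sqrt(np.clip(s, 0, None))
    return area


def _offspring_positions(
    rng: np.random.Generator,
    parents: np.ndarray,
    counts: np.ndarray,
    niche_radius: float,
    core_radius: float,
) -> np.ndarray:
    """Uniform draws in each parent's niche disc, rejected back into the core."""
    centers = np.repeat(parents, counts, axis=0)
    n = len(centers)
    pos = centers + _uniform_disc(rng, n, niche_radius)
    for _ in range(200):
        outside = np.einsum("ij,ij->i", pos, pos) > core_radius**2
        if not outside.any():
            break
        k = int(outside.sum())
        pos[outside] = centers[outside] + _uniform_disc(rng, k, niche_radius)
    return pos


def generate_core(config: SyntheticConfig, core_index: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one TMA core as a (cell table, ground truth) pair.

    Cell coordinates are in µm with origin at the corner of the core's
    bounding box (the disc centre sits at (R, R)).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(core_index)]))
    R = config.radius_um
    props = _core_proportions(config, core_index)
    labels_pool = sorted(props)
    pvec = np.array([props[p] for p in labels_pool], dtype=float)
    pvec = pvec / pvec.sum() if pvec.sum() > 0 else pvec

    # background: homogeneous Poisson on the disc
    n_bg = int(rng.poisson(config.background_density * config.core_area_mm2))
    bg_pos = _uniform_disc(rng, n_bg, R)
    bg_labels = (
        rng.choice(labels_pool, size=n_bg, p=pvec) if n_bg else np.empty(0, dtype=object)
    )

    positions = [bg_pos]
    labels = [np.asarray(bg_labels, dtype=object)]

    spec = config.niche_spec
    ref_pos = np.empty((0, 2))
    if spec is not None and spec.n_reference_cells > 0:
        ref_pos = _uniform_disc(rng, spec.n_reference_cells, R)
        positions.append(ref_pos)
        labels.append(np.array([spec.reference_phenotype] * spec.n_reference_cells, dtype=object))
        # expected offspring scale with each parent's niche area inside the
        # core, so in-niche density is uniformly enrichment × background
        clipped_mm2 = _clipped_niche_area_um2(ref_pos, spec.niche_radius_um, R) / 1e6
        for pheno in sorted(spec.enrichment):
            e = spec.enrichment[pheno]
            if e > 1.0:
                lam = (e - 1.0) * config.background_density * props.get(pheno, 0.0) * clipped_mm2
                counts = rng.poisson(lam)
                if counts.sum():
                    off = _offspring_positions(rng, ref_pos, counts, spec.niche_radius_um, R)
                    positions.append(off)
                    labels.append(np.array([pheno] * len(off), dtype=object))
            elif e < 1.0 and n_bg:
                # thin background cells of this phenotype inside any niche
                tree = cKDTree(ref_pos)
                is_pheno = labels[0] == pheno
                d, _ = tree.query(bg_pos[is_pheno], k=1)
                drop = (d <= spec.niche_radius_um) & (rng.random(int(is_pheno.sum())) > e)
                keep = np.ones(n_bg, dtype=bool)
                keep[np.flatnonzero(is_pheno)[drop]] = False
                positions[0] = bg_pos = bg_pos[keep]
                labels[0] = labels[0][keep]
                n_bg = len(bg_pos)

    pos = np.vstack(positions) if positions else np.empty((0, 2))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    n = len(pos)

    in_niche = np.zeros(n, dtype=bool)
    is_reference = np.zeros(n, dtype=bool)
    if len(ref_pos):
        tree = cKDTree(ref_pos)
        d, _ = tree.query(pos, k=1)
        in_niche = d <= spec.niche_radius_um
        is_reference[n_bg : n_bg + len(ref_pos)] = True

    core_id = f"C{core_index:03d}"
    patient_id = f"P{core_index:03d}"
    groups = list(config.cancer_groups) if config.cancer_groups else list(panels.CANCER_GROUPS)
    cancer_group = groups[core_index % len(groups)]

    # morphology and intensities
    nucleus = np.exp(
        rng.normal(math.log(config.nucleus_mu_um2), config.nucleus_sigma_log, size=n)
    )
    af_draws = {
        ch: np.exp(
            rng.normal(
                config.autofluorescence_model[ch].mu_af,
                config.autofluorescence_model[ch].sigma_af,
                size=n,
            )
        )
        for ch in config.channels
    }

    # QC contamination: corrupt nucleus size or one channel's autofluorescence
    qc_outlier = rng.random(n) < config.qc_contamination
    idx_bad = np.flatnonzero(qc_outlier)
    if len(idx_bad):
        kind = rng.random(len(idx_bad)) < 0.5
        small = rng.random(len(idx_bad)) < 0.5
        bad_size = np.where(
            small, rng.uniform(1.0, 5.0, len(idx_bad)), rng.uniform(1500.0, 3000.0, len(idx_bad))
        )
        nucleus[idx_bad[kind]] = bad_size[kind]
        ch_pick = rng.integers(0, len(config.channels), size=len(idx_bad))
        for j, ch in enumerate(config.channels):
            sel = idx_bad[(~kind) & (ch_pick == j)]
            af_draws[ch][sel] *= 50.0

    positive_map = panels.positive_marker_map(config.rules)
    positive_map[UNASSIGNED] = frozenset()
    data: dict[str, object] = {
        "cell_id": [f"{core_id}_c{i:05d}" for i in range(n)],
        "core_id": core_id,
        "patient_id": patient_id,
        "cancer_group": cancer_group,
        "x_um": pos[:, 0] + R,
        "y_um": pos[:, 1] + R,
        NUCLEUS_COLUMN: nucleus,
    }
    for ch in config.channels:
        data[af_col(ch)] = af_draws[ch]
    for m in config.markers:
        model = config.intensity_model[m]
        is_pos = np.fromiter(
            (m in positive_map.get(l, frozenset()) for l in lab), dtype=bool, count=n
        )
        mu = np.where(is_pos, model.mu_pos, model.mu_neg)
        sigma = np.where(is_pos, model.sigma_pos, model.sigma_neg)
        signal = np.exp(rng.normal(mu, sigma))
        data[raw_col(m)] = signal + af_draws[config.channel_map[m]]

    cells = pd.DataFrame(data)
    truth_cells = pd.DataFrame(
        {
            "cell_id": data["cell_id"],
            "core_id": core_id,
            "true_phenotype": lab,
            "in_niche": in_niche,
            "is_reference": is_reference,
            "qc_outlier": qc_outlier,
        }
    )
    cls = (
        config.core_classes[core_index % len(config.core_classes)]
        if config.core_classes
        else pd.NA
    )
    truth_cores = pd.DataFrame(
        {
            "core_id": [core_id],
            "patient_id": [patient_id],
            "true_tme_class": [cls],
            "cancer_group": [cancer_group],
        }
    )
    return cells, GroundTruth(cells=truth_cells, cores=truth_cores)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Concatenate :func:`generate_core` over all core indices."""
    tables, t_cells, t_cores = [], [], []
    for i in range(config.n_cores):
        cells, truth = generate_core(config, i)
        tables.append(cells)
        t_cells.append(truth.cells)
        t_cores.append(truth.cores)
    cells = pd.concat(tables, ignore_index=True)
    truth = GroundTruth(
        cells=pd.concat(t_cells, ignore_index=True),
        cores=pd.concat(t_cores, ignore_index=True),
    )
    return cells, truth


def generate_paired_zone_cohort(
    n_patients: int = 20,
    markers: tuple[str, ...] = ("M1", "M2"),
    cell_type: str = "T",
    reference_phenotype: str = "REF",
    n_per_zone: int = 8,
    shift_sigma: float = 0.0,
    shifted_marker: str | None = None,
    mu_log: float = 3.0,
    sigma_log: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Minimal cohort for exercising the paired proximal/distal comparison.

    One core per patient with a single reference cell at the core centre and
    ``n_per_zone`` target cells placed in each of the proximal (5–45 µm) and
    distal (155–195 µm) rings, safely inside the default zone windows.
    Corrected marker intensities are lognormal(``mu_log``, ``sigma_log``);
    when ``shift_sigma`` is non-zero the proximal cells of
    ``shifted_marker`` have their log-mean raised by
    ``shift_sigma × sigma_log`` (a shift of that many intensity SDs on the
    log scale).  With ``shift_sigma = 0`` the proximal and distal
    distributions are identical — the null case for calibration studies.

    This bypasses the full TMA generator deliberately: it pins every cell's
    zone by construction, which is what power/calibration simulations need.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if shifted_marker is not None and shifted_marker not in markers:
        raise ConfigurationError(f"shifted_marker {shifted_marker!r} not in markers")
    rows = []
    for p in range(n_patients):
        pid, cid = f"P{p:03d}", f"C{p:03d}"
        rows.append(
            {
                "cell_id": f"{cid}_ref",
                "core_id": cid,
                "patient_id": pid,
                "x_um": 500.0,
                "y_um": 500.0,
                "phenotype": reference_phenotype,
                **{f"corr_{m}": math.exp(mu_log) for m in markers},
            }
        )
        for zone, (lo, hi) in (("prox", (5.0, 45.0)), ("dist", (155.0, 195.0))):
            r = rng.uniform(lo, hi, n_per_zone)
            th = rng.uniform(0.0, 2.0 * np.pi, n_per_zone)
            for j in range(n_per_zone):
                vals = {}
                for m in markers:
                    mu = mu_log
                    if zone == "prox" and m == shifted_marker:
                        mu += shift_sigma * sigma_log
                    vals[f"corr_{m}"] = float(np.exp(rng.normal(mu, sigma_log)))
                rows.append(
                    {
                        "cell_id": f"{cid}_{zone}{j:02d}",
                        "core_id": cid,
                        "patient_id": pid,
                        "x_um": 500.0 + r[j] * math.cos(th[j]),
                        "y_um": 500.0 + r[j] * math.sin(th[j]),
                        "phenotype": cell_type,
                        **vals,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML config round-trip (structured key-value file for the CLI)


def config_to_yaml(config: SyntheticConfig, path) -> None:
    payload: dict = {
        "n_cores": config.n_cores,
        "core_diameter_mm": config.core_diameter_mm,
        "background_density": config.background_density,
        "phenotype_proportions": dict(config.phenotype_proportions),
        "qc_contamination": config.qc_contamination,
        "nucleus_mu_um2": config.nucleus_mu_um2,
        "nucleus_sigma_log": config.nucleus_sigma_log,
        "seed": config.seed,
        "intensity_model": {
            m: {
                "mu_pos": im.mu_pos,
                "sigma_pos": im.sigma_pos,
                "mu_neg": im.mu_neg,
                "sigma_neg": im.sigma_neg,
            }
            for m, im in config.intensity_model.items()
        },
        "autofluorescence_model": {
            c: {"mu_af": am.mu_af, "sigma_af": am.sigma_af}
            for c, am in config.autofluorescence_model.items()
        },
    }
    if config.niche_spec is not None:
        payload["niche_spec"] = {
            "reference_phenotype": config.niche_spec.reference_phenotype,
            "n_reference_cells": config.niche_spec.n_reference_cells,
            "niche_radius_um": config.niche_spec.niche_radius_um,
            "enrichment": dict(config.niche_spec.enrichment),
        }
    if config.core_classes is not None:
        payload["core_classes"] = list(config.core_classes)
    if config.cancer_groups is not None:
        payload["cancer_groups"] = list(config.cancer_groups)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path, seed: int | None = None) -> SyntheticConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "n_cores",
        "core_diameter_mm",
        "background_density",
        "phenotype_proportions",
        "qc_contamination",
        "nucleus_mu_um2",
        "nucleus_sigma_log",
        "seed",
        "core_classes",
        "cancer_groups",
    ):
        if key in payload:
            kwargs[key] = payload[key]
    if "intensity_model" in payload:
        kwargs["intensity_model"] = {
            m: MarkerIntensityModel(**v) for m, v in payload["intensity_model"].items()
        }
    if "autofluorescence_model" in payload:
        kwargs["autofluorescence_model"] = {
            c: ChannelAFModel(**v) for c, v in payload["autofluorescence_model"].items()
        }
    if "niche_spec" in payload and payload["niche_spec"] is not None:
        kwargs["niche_spec"] = NicheSpec(**payload["niche_spec"])
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticConfig(**kwargs)
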