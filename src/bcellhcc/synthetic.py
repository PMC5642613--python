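"""Synthetic cohort generators.

Three generators stand in for the study's cohorts so every downstream
stage is testable without any download:

* a pan-cancer discovery cohort: a multi-entity expression matrix with
  planted co-regulated gene modules against uncorrelated background
  genes (module co-expression induced by one shared latent factor per
  module with equal loadings, so the expected pairwise correlation is
  loading^2 / (loading^2 + noise_sd^2));
* a two-platform validation cohort: paired tumor/non-tumor arrays for
  each patient, a subset of module genes that stays co-regulated, an
  overexpression shift in the "high" patient half, and exponential
  survival whose hazard carries a configurable true hazard ratio for
  the low-expression group, administratively censored;
* an immunohistochemistry cohort: overdispersed per-region B-cell
  counts (patient-level gamma intensity, Poisson field counts) matched
  to configured mean/SEM pairs, coupled across markers and regions by a
  Gaussian copula on one latent infiltration factor, with survival and
  immunoglobulin-positivity links to that infiltration.

Every generator is deterministic given its seed and returns a truth
table sufficient to score downstream recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import packaged_config
from .matrix import ExpressionMatrix, make_annotations, TUMOR, NON_TUMOR
from .records import IHCCountRecord, SurvivalRecord, HIGH, LOW, REGIONS

log = logging.getLogger("bcellhcc")


def _loading(within_cc: float, noise_sd: float) -> float:
    """Factor loading giving expected pairwise CC = within_cc."""
    if not 0 < within_cc < 1:
        raise ValidationError(f"within_cc must be in (0,1), got {within_cc}")
    return noise_sd * np.sqrt(within_cc / (1.0 - within_cc))


# --------------------------------------------------------------------------
# pan-cancer discovery cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleSpec:
    size: int
    within_cc: float

    def __post_init__(self):
        if self.size < 2:
            raise ValidationError(f"module size must be >= 2, "
                                  f"got {self.size}")
        if not 0 < self.within_cc < 1:
            raise ValidationError(f"within_cc must be in (0,1), "
                                  f"got {self.within_cc}")


@dataclass
class PanCancerConfig:
    """Discovery-cohort generator parameters."""

    n_background_genes: int = 475
    planted_modules: tuple = (ModuleSpec(42, 0.9), ModuleSpec(25, 0.9))
    n_samples: int = 300
    n_entities: int = 20
    hcc_label: str = "HCC"
    hcc_n_samples: int = 6
    noise_sd: float = 1.0

    def __post_init__(self):
        self.planted_modules = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m)
            for m in self.planted_modules
        )
        if self.hcc_n_samples >= self.n_samples:
            raise ValidationError("hcc_n_samples must be < n_samples")
        if self.n_entities < 1:
            raise ValidationError("need at least one entity")

    @property
    def n_genes(self) -> int:
        return self.n_background_genes + sum(m.size
                                             for m in self.planted_modules)

    @classmethod
    def from_dict(cls, d: dict) -> "PanCancerConfig":
        return cls(**d)

    @classmethod
    def default(cls) -> "PanCancerConfig":
        return cls.from_dict(packaged_config("discovery")["pan_cancer"])


def module_gene_ids(module_index: int, size: int) -> list[str]:
    """Canonical gene ids for planted module ``module_index`` (1-based)."""
    return [f"MOD{module_index:02d}_G{i:03d}" for i in range(1, size + 1)]


@dataclass
class PanCancerCohort:
    matrix: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, module (0 = background)

    def module_genes(self, module_index: int) -> list[str]:
        sel = self.truth["module"] == module_index
        return self.truth.loc[sel, "gene_id"].tolist()


def generate_pancancer_cohort(config: PanCancerConfig,
                              seed: int) -> PanCancerCohort:
    """Simulate the multi-entity discovery matrix (log-scale values)."""
    total_module = sum(m.size for m in config.planted_modules)
    if total_module > config.n_genes:
        raise ValidationError("module sizes exceed total gene count")
    rng = np.random.default_rng(seed)
    n = config.n_samples

    blocks, gene_ids, truth_rows = [], [], []
    for mi, spec in enumerate(config.planted_modules, start=1):
        lam = _loading(spec.within_cc, config.noise_sd)
        factor = rng.normal(size=n)
        noise = rng.normal(scale=config.noise_sd, size=(spec.size, n))
        blocks.append(lam * factor[None, :] + noise)
        ids = module_gene_ids(mi, spec.size)
        gene_ids.extend(ids)
        truth_rows.extend({"gene_id": g, "module": mi} for g in ids)
    bg = rng.normal(scale=config.noise_sd,
                    size=(config.n_background_genes, n))
    blocks.append(bg)
    bg_ids = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    gene_ids.extend(bg_ids)
    truth_rows.extend({"gene_id": g, "module": 0} for g in bg_ids)

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    entities = [config.hcc_label] * config.hcc_n_samples
    others = max(config.n_entities - 1, 1)
    for i in range(n - config.hcc_n_samples):
        entities.append(f"ENT{(i % others) + 1:02d}")
    ann = make_annotations(sample_ids, entity=entities,
                           tissue=[TUMOR] * n,
                           patient_id=sample_ids)
    values = pd.DataFrame(np.vstack(blocks),
                          index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)
    matrix = ExpressionMatrix(values, ann)
    log.info("pan-cancer cohort: %d genes x %d samples, %d planted modules",
             matrix.n_genes, n, len(config.planted_modules))
    return PanCancerCohort(matrix, pd.DataFrame(truth_rows))


# --------------------------------------------------------------------------
# two-platform validation cohort with survival
# --------------------------------------------------------------------------

@dataclass
class PlatformSpec:
    label: str
    loc: float = 0.0
    scale: float = 1.0


@dataclass
class ValidationConfig:
    """Validation-cohort generator parameters.

    ``overexpression_effect`` is the mean tumor minus non-tumor shift
    (log2 units) of the retained module genes in the high patient
    subset; ``retained_within_cc`` the target pairwise correlation of
    retained genes across tumor arrays (the group shift itself supplies
    part of it, a shared per-array factor the rest); ``true_hr`` the
    hazard of the low- relative to the high-expression group.
    """

    n_patients: int = 242
    module_size: int = 42
    retained_coregulated_count: int = 10
    n_background_genes: int = 1000
    platforms: tuple = (PlatformSpec("U133A2", 0.0, 1.0),
                        PlatformSpec("HTU133A", 0.5, 1.15))
    overexpression_effect: float = 6.5
    retained_within_cc: float = 0.914
    high_fraction: float = 0.5
    true_hr: float = 1.5
    baseline_hazard: float = 0.0116
    censor_time_months: float = 96.0
    baseline_level: float = 8.0

    def __post_init__(self):
        self.platforms = tuple(
            p if isinstance(p, PlatformSpec) else PlatformSpec(**p)
            for p in self.platforms
        )
        if len(self.platforms) != 2:
            raise ValidationError("exactly two platforms are required")
        if not 0 < self.retained_coregulated_count <= self.module_size:
            raise ValidationError(
                "retained_coregulated_count must be in [1, module_size]"
            )
        if self.true_hr <= 0:
            raise ValidationError(f"true_hr must be > 0, got {self.true_hr}")
        if not 0 < self.high_fraction < 1:
            raise ValidationError("high_fraction must be in (0,1)")
        if self.baseline_hazard <= 0 or self.censor_time_months <= 0:
            raise ValidationError("hazard and censor time must be > 0")

    @property
    def module_gene_ids(self) -> list[str]:
        return module_gene_ids(1, self.module_size)

    def factor_loading(self) -> float:
        """Loading of the shared tumor-array factor on retained genes.

        Solves cc = (delta^2/4 + lambda^2) / (delta^2/4 + lambda^2 + 1)
        for lambda, where delta^2/4 is the between-group variance the
        overexpression shift contributes at a balanced split.
        """
        shift_var = (self.overexpression_effect ** 2
                     * self.high_fraction * (1 - self.high_fraction))
        lam2 = (self.retained_within_cc / (1 - self.retained_within_cc)
                - shift_var)
        if lam2 < 0:
            raise ValidationError(
                "retained_within_cc below the correlation the "
                "overexpression shift alone induces; increase it or "
                "lower overexpression_effect"
            )
        return float(np.sqrt(lam2))

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationConfig":
        return cls(**d)

    @classmethod
    def default(cls) -> "ValidationConfig":
        return cls.from_dict(packaged_config("validation")["validation"])


@dataclass
class ValidationCohort:
    matrix: ExpressionMatrix           # paired tumor/non-tumor arrays
    survival: list                     # SurvivalRecord with true group
    patient_truth: pd.DataFrame        # patient_id, true_group, platform
    gene_truth: pd.DataFrame           # gene_id, retained


def generate_validation_cohort(config: ValidationConfig,
                               seed: int) -> ValidationCohort:
    rng = np.random.default_rng(seed)
    n = config.n_patients
    patients = [f"P{i:03d}" for i in range(1, n + 1)]
    high = rng.random(n) < config.high_fraction
    if high.all() or not high.any():
        raise ValidationError("degenerate draw: one survival group empty; "
                              "use a larger cohort")
    half = n // 2
    platform = np.array([config.platforms[0].label] * half
                        + [config.platforms[1].label] * (n - half))

    gene_ids = list(config.module_gene_ids)
    retained = gene_ids[:config.retained_coregulated_count]
    bg_ids = [f"VBG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    all_genes = gene_ids + bg_ids
    lam = config.factor_loading()
    delta = config.overexpression_effect
    base = config.baseline_level

    n_arrays = 2 * n
    sample_ids, tissues, pat_col, plat_col = [], [], [], []
    for p, plat in zip(patients, platform):
        sample_ids += [f"{p}_T", f"{p}_N"]
        tissues += [TUMOR, NON_TUMOR]
        pat_col += [p, p]
        plat_col += [plat, plat]

    X = base + rng.normal(size=(len(all_genes), n_arrays))
    r_idx = [all_genes.index(g) for g in retained]
    # shared per-array co-expression factor on retained genes
    factor = rng.normal(size=n_arrays)
    X[np.ix_(r_idx, range(n_arrays))] += lam * factor[None, :]
    # overexpression of retained genes in tumor arrays of high patients
    tumor_cols = np.arange(0, n_arrays, 2)
    high_tumor = tumor_cols[high]
    X[np.ix_(r_idx, high_tumor)] += delta

    # per-platform location/scale distortion (removed downstream by
    # quantile normalization)
    spec_by_label = {p.label: p for p in config.platforms}
    for j, plat in enumerate(plat_col):
        spec = spec_by_label[plat]
        X[:, j] = spec.loc + spec.scale * X[:, j]

    ann = make_annotations(sample_ids, platform=plat_col, tissue=tissues,
                           patient_id=pat_col)
    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=pd.Index(all_genes, name="gene_id"),
                     columns=sample_ids), ann)

    hazard = config.baseline_hazard * np.where(high, 1.0, config.true_hr)
    raw_t = rng.exponential(1.0 / hazard)
    time = np.minimum(raw_t, config.censor_time_months)
    event = (raw_t <= config.censor_time_months).astype(int)
    survival = [
        SurvivalRecord(p, float(t), int(e), HIGH if h else LOW)
        for p, t, e, h in zip(patients, time, event, high)
    ]
    patient_truth = pd.DataFrame({
        "patient_id": patients,
        "true_group": np.where(high, HIGH, LOW),
        "platform": platform,
    })
    gene_truth = pd.DataFrame({
        "gene_id": all_genes,
        "retained": [g in set(retained) for g in all_genes],
    })
    log.info("validation cohort: %d patients (%d high / %d low), "
             "%d genes, true HR %.3g", n, int(high.sum()),
             int((~high).sum()), len(all_genes), config.true_hr)
    return ValidationCohort(matrix, survival, patient_truth, gene_truth)


# --------------------------------------------------------------------------
# IHC cohort
# --------------------------------------------------------------------------

@dataclass
class IHCConfig:
    """IHC-cohort generator parameters.

    ``region_means`` maps marker -> region -> (mean, SEM) in cells per
    high-power field; the implied per-patient sd is SEM * sqrt(n).
    ``survival_link`` gives the hazard ratio of high vs low infiltration
    per region (CD20-defined, mean-split on the patient-level
    intensities). ``positivity_link`` gives P(immunoglobulin positive)
    per region given Im-high/Im-low status.
    """

    n_patients: int = 119
    count_family: str = "negative_binomial"
    latent_corr: float = 0.6
    region_means: dict = field(default_factory=lambda: {
        "CD20": {"Tu": (8.0, 2.0), "Im": (65.0, 5.0), "Sd": (25.0, 3.0)},
        "CD79a": {"Tu": (13.0, 3.0), "Im": (62.0, 7.0), "Sd": (23.0, 3.0)},
    })
    survival_link: dict = field(default_factory=lambda: {
        "Tu": 0.85, "Im": 0.5, "Sd": 1.6})
    baseline_hazard: float = 0.01475
    censor_time_months: float = 120.0
    positivity_link: dict = field(default_factory=lambda: {
        "p_high": {"Tu": 0.8, "Im": 0.85, "Sd": 0.25},
        "p_low": {"Tu": 0.1, "Im": 0.15, "Sd": 0.2}})
    covariates: dict = field(default_factory=lambda: {
        "female_fraction": 0.2185, "age_mean": 65.0, "age_sd": 9.6,
        "t_stage_high_p": 0.4, "bridging_p": 0.2, "hep_b_p": 0.15,
        "hep_c_p": 0.25, "cirrhosis_p_im_high": 0.75,
        "cirrhosis_p_im_low": 0.45})

    def __post_init__(self):
        if self.count_family not in ("negative_binomial",
                                     "lognormal_rounded"):
            raise ValidationError(
                f"unknown count family {self.count_family!r}"
            )
        if not 0 <= self.latent_corr < 1:
            raise ValidationError("latent_corr must be in [0,1)")
        for marker, regions in self.region_means.items():
            self.region_means[marker] = {
                r: tuple(v) for r, v in regions.items()}
            for region, (mean, sem) in self.region_means[marker].items():
                if mean < 0 or sem <= 0:
                    raise ValidationError(
                        f"{marker}/{region}: mean must be >= 0 and SEM > 0"
                    )

    def patient_sd(self, marker: str, region: str) -> float:
        mean, sem = self.region_means[marker][region]
        return sem * np.sqrt(self.n_patients)

    @classmethod
    def from_dict(cls, d: dict) -> "IHCConfig":
        return cls(**d)

    @classmethod
    def default(cls) -> "IHCConfig":
        return cls.from_dict(packaged_config("ihc")["ihc"])


@dataclass
class IHCCohort:
    records: list
    survival: list
    truth: pd.DataFrame  # per-patient latent factor, region-high flags


def _intensity_ppf(u: np.ndarray, mean: float, var: float,
                   family: str) -> np.ndarray:
    """Quantile function of the patient-level intensity distribution."""
    if family == "negative_binomial":
        shape = mean ** 2 / var
        scale = var / mean
        return sps.gamma.ppf(u, a=shape, scale=scale)
    # lognormal matched to (mean, var)
    sigma2 = np.log(1.0 + var / mean ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return sps.lognorm.ppf(u, s=np.sqrt(sigma2), scale=np.exp(mu))


def generate_ihc_cohort(config: IHCConfig, seed: int) -> IHCCohort:
    """Simulate the resection cohort's count, positivity and survival data.

    Counts: per patient/marker/region a latent intensity G (gamma or
    lognormal, mean m, variance sd^2 - m/3 with sd = SEM * sqrt(n)) and
    three Poisson(G) field counts, so the three-field mean has mean m
    and cohort-level SEM as configured. Intensities are coupled through
    one latent infiltration factor (Gaussian copula, loading
    ``latent_corr``).
    """
    rng = np.random.default_rng(seed)
    n = config.n_patients
    rho = config.latent_corr
    markers = list(config.region_means)

    # feasibility of the variance decomposition
    for m in markers:
        for r, (mean, sem) in config.region_means[m].items():
            var = (sem * np.sqrt(n)) ** 2 - mean / 3.0
            if config.count_family == "negative_binomial" and var <= 0:
                raise ValidationError(
                    f"{m}/{r}: implied intensity variance "
                    f"{var:.3g} <= 0; counts are underdispersed for the "
                    f"negative binomial family -- use 'lognormal_rounded'"
                )

    patients = [f"R{i:03d}" for i in range(1, n + 1)]
    z = rng.normal(size=n)  # latent B-cell infiltration factor

    intensity = {}  # (marker, region) -> per-patient intensity
    for m in markers:
        for r, (mean, sem) in config.region_means[m].items():
            eps = rng.normal(size=n)
            u = sps.norm.cdf(rho * z + np.sqrt(1 - rho ** 2) * eps)
            var = (sem * np.sqrt(n)) ** 2 - mean / 3.0
            var = max(var, 1e-9)
            intensity[(m, r)] = _intensity_ppf(u, mean, var,
                                               config.count_family)

    counts = {key: rng.poisson(lam[:, None], size=(n, 3))
              for key, lam in intensity.items()}

    # true per-region high/low status from the CD20 intensities
    region_high = {}
    for r in REGIONS:
        lam = intensity[("CD20", r)]
        region_high[r] = lam > lam.mean()

    # immunoglobulin positivity linked to Im infiltration
    p_high = config.positivity_link["p_high"]
    p_low = config.positivity_link["p_low"]
    im_high = region_high["Im"]
    kappa = {r: rng.random(n) < np.where(im_high, p_high[r], p_low[r])
             for r in REGIONS}
    igm = {r: rng.random(n) < np.where(im_high, p_high[r], p_low[r])
           for r in REGIONS}

    # clinical covariates
    cv = config.covariates
    female = rng.random(n) < cv["female_fraction"]
    age = np.round(rng.normal(cv["age_mean"], cv["age_sd"], size=n), 1)
    t_stage = rng.random(n) < cv["t_stage_high_p"]
    bridging = rng.random(n) < cv["bridging_p"]
    hep_b = rng.random(n) < cv["hep_b_p"]
    hep_c = rng.random(n) < cv["hep_c_p"]
    cirrhosis = rng.random(n) < np.where(im_high,
                                         cv["cirrhosis_p_im_high"],
                                         cv["cirrhosis_p_im_low"])

    covar_rows = [{
        "gender": "F" if female[i] else "M",
        "age": float(age[i]),
        "t_stage_high": int(t_stage[i]),
        "bridging_therapy": int(bridging[i]),
        "hepatitis_b": int(hep_b[i]),
        "hepatitis_c": int(hep_c[i]),
        "cirrhosis": int(cirrhosis[i]),
    } for i in range(n)]

    records = []
    for i, p in enumerate(patients):
        for m in markers:
            for r in REGIONS:
                c = counts[(m, r)][i]
                records.append(IHCCountRecord(
                    p, m, r, (float(c[0]), float(c[1]), float(c[2])),
                    kappa_positive=bool(kappa[r][i]),
                    igm_positive=bool(igm[r][i]),
                    covariates=dict(covar_rows[i]),
                ))

    # survival linked to per-region infiltration
    log_mult = np.zeros(n)
    for r, hr in config.survival_link.items():
        log_mult += np.log(hr) * region_high[r]
    hazard = config.baseline_hazard * np.exp(log_mult)
    raw_t = rng.exponential(1.0 / hazard)
    time = np.minimum(raw_t, config.censor_time_months)
    event = (raw_t <= config.censor_time_months).astype(int)
    survival = [SurvivalRecord(p, float(t), int(e))
                for p, t, e in zip(patients, time, event)]

    truth = pd.DataFrame({
        "patient_id": patients,
        "latent_factor": z,
        **{f"{r}_high": region_high[r] for r in REGIONS},
        "hazard": hazard,
    })
    log.info("IHC cohort: %d patients, %d count records", n, len(records))
    return IHCCohort(records, survival, truth)
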