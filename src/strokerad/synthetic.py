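"""Synthetic cohorts and CT-like phantoms.

No public CT dataset accompanies the problem this package addresses, so every
downstream stage is exercised on seeded synthetic data:

* clinical covariates drawn per onset-time stratum (early = onset-to-imaging
  <= 4.5 h, late = > 4.5 h) from distributions calibrated to the published
  stratum summaries (means/SDs, medians/IQRs, prevalences),
* CT-like phantom volumes with a hemispheric MCA-territory VOI and an
  ellipsoidal hypodense lesion whose density decrement and textural
  heterogeneity depend on the stratum, and whose extent grows as ASPECTS
  falls,
* rater-style mask perturbation for reliability (ICC) studies.

All draws are reproducible: identical seeds give bit-identical cohorts,
phantoms, perturbations and splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, optimize, stats

from ._utils import DEFAULT_SEED, check_in_unit_interval, check_positive, rng_from
from .preprocessing import CTVolume, VOIMask

EARLY = "early"
LATE = "late"

# Integer probability vectors on ASPECTS 0..10, constructed so the implied
# median (IQR) hits the published stratum anchors: early 8 (Q1 5, Q3 9),
# late 6 (Q1 3, Q3 9).
ASPECTS_PMF_EARLY = (0.01, 0.02, 0.03, 0.05, 0.08, 0.09, 0.09, 0.11, 0.19, 0.19, 0.14)
ASPECTS_PMF_LATE = (0.03, 0.06, 0.08, 0.09, 0.08, 0.08, 0.09, 0.08, 0.09, 0.17, 0.15)

# Collateral grade 0..3; median (IQR) = 1 (1-1) in both strata.
COLLATERAL_PMF = (0.10, 0.75, 0.10, 0.05)


@dataclass
class ClinicalCovariates:
    age: float
    sex: str  # {male, female}
    nihss: int
    aspects: int
    hypertension: bool
    diabetes: bool
    hyperlipidemia: bool
    atrial_fibrillation: bool
    smoking: bool
    alcohol: bool
    hvs: bool
    ica_occlusion: bool
    collateral_grade: int
    side: str  # {left, right}

    def __post_init__(self):
        if not 0 <= self.aspects <= 10:
            raise ValueError(f"aspects must be in [0, 10], got {self.aspects}")
        if not 0 <= self.nihss <= 42:
            raise ValueError(f"nihss must be in [0, 42], got {self.nihss}")
        if self.collateral_grade not in (0, 1, 2, 3):
            raise ValueError(f"collateral_grade must be 0..3, got {self.collateral_grade}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class SubjectRecord:
    id: str
    tfs_class: str  # {early, late}
    covariates: ClinicalCovariates
    split: str = "unassigned"  # {development, validation, external, unassigned}

    def __post_init__(self):
        if self.tfs_class not in (EARLY, LATE):
            raise ValueError(f"tfs_class must be early/late, got {self.tfs_class!r}")


@dataclass
class StratumParams:
    """Per-stratum covariate distribution parameters."""

    age_mean: float
    age_sd: float
    nihss_median: float
    nihss_q1: float
    nihss_q3: float
    aspects_pmf: tuple[float, ...]
    prevalence: dict = field(default_factory=dict)  # boolean covariates + male + right side
    collateral_pmf: tuple[float, ...] = COLLATERAL_PMF

    def validate(self) -> None:
        check_positive("age_sd", self.age_sd)
        check_in_unit_interval("prevalences", list(self.prevalence.values()))
        for pmf in (self.aspects_pmf, self.collateral_pmf):
            if abs(sum(pmf) - 1.0) > 1e-9 or min(pmf) < 0:
                raise ValueError("probability vector must be nonnegative and sum to 1")


def _default_early() -> StratumParams:
    return StratumParams(
        age_mean=75.17,
        age_sd=12.39,
        nihss_median=19.5,
        nihss_q1=16.0,
        nihss_q3=22.25,
        aspects_pmf=ASPECTS_PMF_EARLY,
        prevalence={
            "male": 0.6739,
            "hypertension": 0.6739,
            "diabetes": 0.1957,
            "hyperlipidemia": 0.2609,
            "atrial_fibrillation": 0.5435,
            "smoking": 0.3261,
            "alcohol": 0.2174,
            "hvs": 0.6087,
            "right_side": 0.4130,
            "ica_occlusion": 0.4130,
        },
    )


def _default_late() -> StratumParams:
    return StratumParams(
        age_mean=70.12,
        age_sd=12.97,
        nihss_median=19.0,
        nihss_q1=13.0,
        nihss_q3=25.0,
        aspects_pmf=ASPECTS_PMF_LATE,
        prevalence={
            "male": 0.6104,
            "hypertension": 0.6494,
            "diabetes": 0.1818,
            "hyperlipidemia": 0.1948,
            "atrial_fibrillation": 0.4675,
            "smoking": 0.3506,
            "alcohol": 0.2078,
            "hvs": 0.5065,
            "right_side": 0.5844,
            "ica_occlusion": 0.4156,
        },
    )


@dataclass
class CohortSpec:
    """Replica-mode cohort: exact stratum sizes, per-stratum distributions.

    ``mode="replica"`` draws exactly n_early / n_late subjects per stratum so
    composition is deterministic; ``mode="sampling"`` assigns each subject's
    stratum by a Bernoulli draw with prevalence n_early/(n_early+n_late).
    """

    n_early: int = 46
    n_late: int = 77
    early: StratumParams = field(default_factory=_default_early)
    late: StratumParams = field(default_factory=_default_late)
    age_bounds: tuple[float, float] = (18.0, 100.0)
    seed: int = DEFAULT_SEED
    mode: str = "replica"

    def validate(self) -> None:
        if self.n_early < 0 or self.n_late < 0 or self.n_early + self.n_late == 0:
            raise ValueError("stratum counts must be nonnegative with positive total")
        if self.mode not in ("replica", "sampling"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.early.validate()
        self.late.validate()


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) whose [lo, hi]-truncation has the given mean/SD.

    Truncating a normal shifts its moments; solving for the parent keeps the
    generated sample calibrated to the configured mean/SD.
    """

    def eqs(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(eqs, x0=[mean, math.log(sd)], tol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) from median and quartiles (right-skewed score)."""
    z75 = stats.norm.ppf(0.75)
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * z75)
    return mu, sigma


def _draw_covariates(params: StratumParams, bounds, rng: np.random.Generator) -> ClinicalCovariates:
    lo, hi = bounds
    mu, sigma = _truncnorm_parent(params.age_mean, params.age_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    age = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))

    nmu, nsigma = _lognormal_params(params.nihss_median, params.nihss_q1, params.nihss_q3)
    nihss = int(np.clip(round(float(rng.lognormal(nmu, nsigma))), 0, 42))

    aspects = int(rng.choice(11, p=params.aspects_pmf))
    collateral = int(rng.choice(len(params.collateral_pmf), p=params.collateral_pmf))
    p = params.prevalence
    draw = {k: bool(rng.random() < p[k]) for k in sorted(p)}
    return ClinicalCovariates(
        age=age,
        sex="male" if draw["male"] else "female",
        nihss=nihss,
        aspects=aspects,
        hypertension=draw["hypertension"],
        diabetes=draw["diabetes"],
        hyperlipidemia=draw["hyperlipidemia"],
        atrial_fibrillation=draw["atrial_fibrillation"],
        smoking=draw["smoking"],
        alcohol=draw["alcohol"],
        hvs=draw["hvs"],
        ica_occlusion=draw["ica_occlusion"],
        collateral_grade=collateral,
        side="right" if draw["right_side"] else "left",
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a seeded cohort; same spec (incl. seed) -> identical cohort."""
    spec.validate()
    total = spec.n_early + spec.n_late
    if spec.mode == "replica":
        classes = [EARLY] * spec.n_early + [LATE] * spec.n_late
    else:
        rng_cls = rng_from(spec.seed, "class-assignment")
        prev = spec.n_early / total
        classes = [EARLY if u < prev else LATE for u in rng_cls.random(total)]
    records = []
    for i, cls in enumerate(classes):
        rng = rng_from(spec.seed, "subject", i, cls)
        params = spec.early if cls == EARLY else spec.late
        cov = _draw_covariates(params, spec.age_bounds, rng)
        records.append(SubjectRecord(id=f"S{i:05d}", tfs_class=cls, covariates=cov))
    return records


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """CT-like phantom: hemispheric VOI, ellipsoidal hypodense lesion.

    The lesion is more hypodense and more heterogeneous in the late stratum,
    emulating the progression of ischemic density change; its volume fraction
    of the VOI grows as ASPECTS falls. Between-subject random effects
    (baseline density, lesion decrement, texture level, VOI size) keep the
    class distributions overlapping, as subtle early ischemic change is; VOI
    size shrinks mildly with age, emulating atrophy of the MCA territory.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = 35.0
    background_sd: float = 2.0
    lesion_decrement: dict = field(default_factory=lambda: {EARLY: 2.0, LATE: 4.0})
    texture_sd: dict = field(default_factory=lambda: {EARLY: 1.5, LATE: 2.5})
    correlation_length_mm: float = 1.5
    extent_fraction_range: tuple[float, float] = (0.05, 0.60)
    # between-subject biological variability
    background_between_sd: float = 1.5  # HU
    decrement_between_sd: float = 2.0  # HU
    texture_rel_sd: float = 0.3  # lognormal spread of the texture level
    voi_scale: float = 0.45  # ellipsoid semi-axes as fraction of grid
    voi_age_slope: float = -0.003  # relative VOI scale per year from age 70
    voi_scale_jitter: float = 0.04  # subject-level relative SD
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        check_positive("spacing", self.spacing)
        check_positive("shape", self.shape)
        if abs(self.lesion_decrement[EARLY]) > abs(self.lesion_decrement[LATE]):
            raise ValueError("early decrement magnitude must be <= late")
        f0, f1 = self.extent_fraction_range
        if not (0 < f0 <= f1 <= 1):
            raise ValueError("extent fractions must lie in (0, 1]")

    def extent_fraction(self, aspects: int) -> float:
        """Lesion volume as a fraction of the VOI: lower ASPECTS -> larger."""
        f0, f1 = self.extent_fraction_range
        return f0 + (f1 - f0) * (10 - aspects) / 10.0


def voi_template(shape, side: str = "right", scale: float = 0.45) -> np.ndarray:
    """Hemispheric VOI: ellipsoid scaled to the volume, cut at the midline."""
    nx, ny, nz = shape
    ii, jj, kk = np.indices(shape)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = ((ii - cx) / (scale * nx)) ** 2 + ((jj - cy) / (scale * ny)) ** 2 + (
        (kk - cz) / (scale * nz)
    ) ** 2
    mask = r <= 1.0
    if side == "right":
        mask &= ii >= cx
    else:
        mask &= ii <= cx
    return mask


def _smooth_noise(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled back to unit variance."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_phantom(
    record: SubjectRecord, pspec: PhantomSpec, return_lesion: bool = False
):
    """Render one subject's phantom; deterministic in (record.id, pspec.seed).

    With ``return_lesion`` the boolean lesion support is returned as a third
    element (useful for effect-direction checks).
    """
    pspec.validate()
    rng = rng_from(pspec.seed, "phantom", record.id)
    shape = tuple(pspec.shape)
    sigma_vox = pspec.correlation_length_mm / np.asarray(pspec.spacing)

    # subject-level random effects (drawn first so voxel noise follows)
    bg = pspec.background_hu + pspec.background_between_sd * rng.standard_normal()
    dec = pspec.lesion_decrement[record.tfs_class] + (
        pspec.decrement_between_sd * rng.standard_normal()
    )
    tex = pspec.texture_sd[record.tfs_class] * float(
        rng.lognormal(0.0, pspec.texture_rel_sd)
    )
    scale = pspec.voi_scale * (
        1.0 + pspec.voi_age_slope * (record.covariates.age - 70.0)
    ) * (1.0 + pspec.voi_scale_jitter * rng.standard_normal())
    scale = float(np.clip(scale, 0.2, 0.49))

    voi = voi_template(shape, record.covariates.side, scale)
    frac = pspec.extent_fraction(record.covariates.aspects)
    lesion = _lesion_ellipsoid(voi, frac)
    if not lesion.any():
        raise ValueError("lesion extent rule yielded an empty lesion")

    vol = bg + pspec.background_sd * _smooth_noise(shape, sigma_vox, rng)
    vol[lesion] += -dec + tex * _smooth_noise(shape, sigma_vox, rng)[lesion]
    out = CTVolume(vol, pspec.spacing), VOIMask(voi, pspec.spacing)
    return out + (lesion,) if return_lesion else out


def _lesion_ellipsoid(voi: np.ndarray, fraction: float) -> np.ndarray:
    """Ellipsoid centered at the VOI centroid holding ~fraction of VOI voxels.

    Monotone in ``fraction`` by construction: the region is a sublevel set of
    a fixed quadratic, thresholded at the fraction-quantile inside the VOI.
    """
    idx = np.argwhere(voi)
    centroid = idx.mean(axis=0)
    half = np.maximum((idx.max(axis=0) - idx.min(axis=0)) / 2.0, 1.0)
    ii, jj, kk = np.indices(voi.shape)
    q = (
        ((ii - centroid[0]) / half[0]) ** 2
        + ((jj - centroid[1]) / half[1]) ** 2
        + ((kk - centroid[2]) / half[2]) ** 2
    )
    inside = q[voi]
    thresh = np.quantile(inside, fraction)
    return voi & (q <= thresh)


def perturb_mask(mask: VOIMask, magnitude: float, seed: int = DEFAULT_SEED) -> VOIMask:
    """Rater-style boundary perturbation of a VOI mask.

    The mask's signed Euclidean distance field (positive inside) is offset by
    a smooth random field scaled by ``magnitude`` (in units of the mask's
    equivalent radius) and re-thresholded. Magnitude 0 returns the identical
    mask; expected Dice overlap with the input decreases as magnitude grows.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    m = mask.voxels
    if magnitude == 0:
        return VOIMask(m.copy(), mask.spacing)
    rng = rng_from(seed, "perturb")
    d_in = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    d_out = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    signed = d_in - d_out
    r_eq = (3 * mask.count * np.prod(mask.spacing) / (4 * np.pi)) ** (1 / 3)
    bump = _smooth_noise(m.shape, 2.0, rng)
    new = (signed + magnitude * r_eq * bump) > 0
    if not new.any():
        raise ValueError("perturbation emptied the mask")
    return VOIMask(new, mask.spacing)


def generate_tabular_cohort(
    n: int = 123,
    n_informative: int = 6,
    n_noise: int = 24,
    feature_effect: float = 0.5,
    age_effect: float = 0.5,
    aspects_effect: float = 0.5,
    prevalence: float = 46 / 123,
    seed: int = DEFAULT_SEED,
):
    """Tabular cohort with a known linear class signal, for recovery studies.

    ``n_informative`` standardized features each carry ``feature_effect`` on
    the logit of the early class; age adds ``age_effect`` per SD (older
    subjects present earlier) and ASPECTS ``aspects_effect`` per SD (higher
    scores in the early stratum). Returns (features DataFrame, clinical
    DataFrame with age/aspects, label array with early = 1).
    """
    import pandas as pd

    rng = rng_from(seed, "tabular")
    p = n_informative + n_noise
    X = rng.standard_normal((n, p))
    age = np.clip(72.0 + 13.0 * rng.standard_normal(n), 18, 100)
    aspects = rng.integers(0, 11, size=n).astype(float)
    z_age = (age - age.mean()) / age.std()
    z_asp = (aspects - aspects.mean()) / aspects.std()
    beta0 = math.log(prevalence / (1 - prevalence))
    eta = (
        beta0
        + feature_effect * X[:, :n_informative].sum(axis=1)
        + age_effect * z_age
        + aspects_effect * z_asp
    )
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    features = pd.DataFrame(
        X,
        columns=[f"signal_{k}" for k in range(n_informative)]
        + [f"noise_{k}" for k in range(n_noise)],
    )
    clinical = pd.DataFrame({"age": age, "aspects": aspects})
    return features, clinical, y


def split_cohort(
    records: list[SubjectRecord],
    n_dev: int,
    n_val: int,
    stratify: bool = True,
    seed: int = DEFAULT_SEED,
) -> list[SubjectRecord]:
    """Assign development/validation split labels in place (and return them).

    Stratified mode apportions each class between splits as closely as
    integer rounding allows (largest-remainder on the development share).
    """
    unassigned = [r for r in records if r.split == "unassigned"]
    if n_dev + n_val != len(unassigned):
        raise ValueError(
            f"n_dev + n_val = {n_dev + n_val} != {len(unassigned)} unassigned records"
        )
    rng = rng_from(seed, "split")
    if not stratify:
        order = rng.permutation(len(unassigned))
        for pos, i in enumerate(order):
            unassigned[i].split = "development" if pos < n_dev else "validation"
        return records

    total = len(unassigned)
    by_class = {}
    for r in unassigned:
        by_class.setdefault(r.tfs_class, []).append(r)
    # largest-remainder apportionment of n_dev across classes
    quotas = {c: len(v) * n_dev / total for c, v in by_class.items()}
    dev_n = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n_dev - sum(dev_n.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - dev_n[c], reverse=True)[:short]:
        dev_n[c] += 1
    for c, members in sorted(by_class.items()):
        order = rng.permutation(len(members))
        for pos, i in enumerate(order):
            members[i].split = "development" if pos < dev_n[c] else "validation"
    return records
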