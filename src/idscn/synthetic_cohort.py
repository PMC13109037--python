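"""Synthetic two-group cohorts with modular covariance in cortical thickness.

The generator emulates a 51-vs-51 smoker (SM) / healthy-control (HC) design:
regional thickness follows a module-factor linear model in which regions
belonging to the same ground-truth module share a latent standard-normal
factor per subject. The factor loading differs by group (``lambda_hc`` vs
``lambda_sm``), so lowering the smoker loading attenuates the modular
covariance structure that the individualized-network analysis is designed to
detect, while a small uniform ``thinning_sm`` term produces diffuse group
thinning. Companion generators produce a dACC metabolite table (with a
calibrated group shift in tNAA only) and behavioral questionnaire scores.

All draws go through one :class:`numpy.random.Generator` stream per table, so
identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DK_REGIONS, GROUP_CONTROL, GROUP_SMOKER, CohortBundle

# Gaussian IQR -> SD conversion: IQR = 2 * Phi^{-1}(0.75) * sd = 1.349 sd.
_IQR_TO_SD = 2.0 * stats.norm.ppf(0.75)

#: Per-metabolite (location, scale) by group, institutional units. tNAA is
#: calibrated to the study's printed group medians/IQRs (HC 17.8, IQR 1.92;
#: SM 16.7, IQR 2.27); the other metabolites carry no group effect.
DEFAULT_METABOLITE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "tNAA": {GROUP_CONTROL: (17.8, 1.92 / _IQR_TO_SD), GROUP_SMOKER: (16.7, 2.27 / _IQR_TO_SD)},
    "Glu": {GROUP_CONTROL: (8.7, 1.1), GROUP_SMOKER: (8.7, 1.1)},
    "GSH": {GROUP_CONTROL: (1.6, 0.35), GROUP_SMOKER: (1.6, 0.35)},
    "GABA": {GROUP_CONTROL: (2.4, 0.5), GROUP_SMOKER: (2.4, 0.5)},
}

#: Behavioral instruments: (HC mean, HC sd, SM mean, SM sd, low, high).
#: HC entries of smoker-only instruments (FTND, QSU) are None.
DEFAULT_BEHAVIOR_PARAMS: dict[str, tuple] = {
    "FTND": (None, None, 4.2, 2.3, 0.0, 10.0),
    "QSU": (None, None, 46.3, 26.5, 10.0, 70.0),
    "BIS_attention": (12.8, 2.4, 13.0, 3.5, 8.0, 32.0),
    "BIS_motor": (20.0, 2.6, 21.4, 4.5, 11.0, 44.0),
    "BIS_nonplanning": (20.8, 4.6, 22.7, 5.3, 11.0, 44.0),
    "PANAS_negative": (14.1, 4.3, 16.0, 7.1, 10.0, 50.0),
    "PANAS_positive": (35.9, 6.9, 35.0, 7.2, 10.0, 50.0),
    "SHAPS": (4.9, 4.1, 5.4, 5.0, 0.0, 14.0),
}


def default_module_partition(n_regions: int, n_modules: int = 4) -> np.ndarray:
    """Contiguous near-equal split of regions into modules (34 -> 9/9/8/8)."""
    if not 1 <= n_modules <= n_regions:
        raise ValueError("need 1 <= n_modules <= n_regions")
    sizes = np.full(n_modules, n_regions // n_modules)
    sizes[: n_regions % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Thickness for subject k, region r:

        t_kr = mu_r + beta_age (age_k - 40) + beta_sex s_k + b_k
               + lambda_{g(k)} u_{m(r),k} + eps_kr - thinning_sm [g(k)=SM]

    with region means ``mu_r ~ U(2, 3)`` mm drawn once per run, subject
    offsets ``b_k ~ N(0, sigma_subject^2)``, module factors
    ``u_{m,k} ~ N(0, 1)`` shared by all regions of module m, and residual
    noise ``eps_kr ~ N(0, sigma_noise^2)``.
    """

    n_per_group: int = 51
    n_regions: int = 34
    module_partition: np.ndarray | None = None
    n_modules: int = 4
    lambda_hc: float = 1.2
    lambda_sm: float = 0.6
    sigma_noise: float = 0.3
    sigma_subject: float = 0.1
    beta_age: float = -0.005
    beta_sex: float = 0.02
    thinning_sm: float = 0.02
    # demographics (age in years, truncated to study eligibility 21-65)
    age_hc: tuple[float, float] = (40.0, 13.0)
    age_sm: tuple[float, float] = (48.0, 12.0)
    age_range: tuple[float, float] = (21.0, 65.0)
    p_female_hc: float = 0.45
    p_female_sm: float = 0.51
    education: tuple[float, float] = (14.0, 2.5)
    education_range: tuple[float, float] = (8.0, 20.0)
    metabolite_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_METABOLITE_PARAMS.items()}
    )
    behavior_params: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("lambda_hc", "lambda_sm", "sigma_noise", "sigma_subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.module_partition is None:
            self.module_partition = default_module_partition(self.n_regions, self.n_modules)
        else:
            self.module_partition = np.asarray(self.module_partition)
        part = self.module_partition
        if part.shape != (self.n_regions,):
            raise ValueError("module_partition must assign every region exactly once")
        self.n_modules = int(part.max()) + 1
        for name, per_group in self.metabolite_params.items():
            for grp, (_, scale) in per_group.items():
                if scale < 0:
                    raise ValueError(f"negative scale for {name}/{grp}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the output tables."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _truncated_normal(
    rng: np.random.Generator,
    loc: float,
    scale: float,
    low: float,
    high: float,
    size: int,
) -> np.ndarray:
    if scale == 0:
        return np.full(size, float(np.clip(loc, low, high)))
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Draw a cohort under the module-factor thickness model.

    Subjects whose draw produces a non-positive thickness anywhere have their
    latent factors and noise redrawn; if a subject still fails after 100
    rounds the call aborts with an explicit error.
    """
    rng = config.rng(0)
    n = config.n_per_group
    groups = np.array([GROUP_CONTROL] * n + [GROUP_SMOKER] * n)
    is_sm = groups == GROUP_SMOKER

    age = np.concatenate(
        [
            _truncated_normal(rng, *config.age_hc, *config.age_range, n),
            _truncated_normal(rng, *config.age_sm, *config.age_range, n),
        ]
    )
    p_female = np.where(is_sm, config.p_female_sm, config.p_female_hc)
    sex = (rng.random(2 * n) < p_female).astype(int)  # 1 = female
    education = _truncated_normal(
        rng, *config.education, *config.education_range, 2 * n
    )

    mu = rng.uniform(2.0, 3.0, config.n_regions)
    lam = np.where(is_sm, config.lambda_sm, config.lambda_hc)
    part = config.module_partition

    fixed = (
        mu[None, :]
        + config.beta_age * (age - 40.0)[:, None]
        + config.beta_sex * sex[:, None]
        - config.thinning_sm * is_sm[:, None]
    )

    def draw_random_part(n_rows: int) -> np.ndarray:
        b = rng.normal(0.0, config.sigma_subject, n_rows)
        u = rng.normal(0.0, 1.0, (n_rows, config.n_modules))
        eps = rng.normal(0.0, config.sigma_noise, (n_rows, config.n_regions))
        return b[:, None] + u[:, part] * lam_block[:, None] + eps

    lam_block = lam
    thickness = fixed + draw_random_part(2 * n)
    for _ in range(100):
        bad = (thickness <= 0).any(axis=1)
        if not bad.any():
            break
        lam_block = lam[bad]
        thickness[bad] = fixed[bad] + draw_random_part(int(bad.sum()))
    else:
        raise RuntimeError(
            "could not draw strictly positive thickness after 100 resampling "
            "rounds; check the scale parameters of the simulation"
        )

    ids = [f"{g}{i % n + 1:03d}" for i, g in enumerate(groups)]
    regions = (
        list(DK_REGIONS)
        if config.n_regions == len(DK_REGIONS)
        else [f"region_{r + 1:02d}" for r in range(config.n_regions)]
    )
    subjects = pd.DataFrame(
        {
            "group": groups,
            "age": age,
            "sex": sex,
            "education": education,
            "global_mean_thickness": thickness.mean(axis=1),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    thick = pd.DataFrame(thickness, index=subjects.index, columns=regions)
    return CohortBundle(subjects, thick, module_partition=part.copy())


def simulate_metabolites(config: SimConfig, cohort: CohortBundle) -> pd.DataFrame:
    """Gaussian dACC metabolite concentrations per subject.

    tNAA carries the calibrated group shift; Glu, GSH and GABA are
    exchangeable between groups. Zero scales give point masses.
    """
    rng = config.rng(1)
    out = {}
    for name, per_group in config.metabolite_params.items():
        values = np.empty(cohort.n_subjects)
        for grp, (loc, scale) in per_group.items():
            mask = (cohort.groups == grp).to_numpy()
            values[mask] = loc + scale * rng.standard_normal(int(mask.sum()))
        out[name] = values
    return pd.DataFrame(out, index=cohort.subjects.index)


def simulate_behavior(config: SimConfig, cohort: CohortBundle) -> pd.DataFrame:
    """Questionnaire scores from range-truncated Gaussians.

    Smoker-only instruments (FTND, QSU) are missing (NaN) for controls by
    design; all other instruments are drawn for everyone with per-group
    location/scale.
    """
    rng = config.rng(2)
    is_sm = (cohort.groups == GROUP_SMOKER).to_numpy()
    out = {}
    for name, (m_hc, s_hc, m_sm, s_sm, low, high) in config.behavior_params.items():
        values = np.full(cohort.n_subjects, np.nan)
        values[is_sm] = _truncated_normal(rng, m_sm, s_sm, low, high, int(is_sm.sum()))
        if m_hc is not None:
            values[~is_sm] = _truncated_normal(
                rng, m_hc, s_hc, low, high, int((~is_sm).sum())
            )
        out[name] = values
    return pd.DataFrame(out, index=cohort.subjects.index)


def expected_cliffs_delta(shift: float, scale_a: float, scale_b: float) -> float:
    """Analytic Cliff's delta for two Gaussian groups, A = B + shift.

    For X ~ N(mu_b + shift, scale_a^2) and Y ~ N(mu_b, scale_b^2),
    P(X > Y) = Phi(shift / sqrt(scale_a^2 + scale_b^2)) and
    delta = 2 P(X > Y) - 1. Used to calibrate the metabolite generator
    against a target effect size.
    """
    if scale_a < 0 or scale_b < 0:
        raise ValueError("scales must be >= 0")
    pooled = math.hypot(scale_a, scale_b)
    if pooled == 0:
        if shift == 0:
            raise ValueError("delta undefined for two identical point masses")
        return math.copysign(1.0, shift)
    return 2.0 * stats.norm.cdf(shift / pooled) - 1.0


def write_tables(
    out_dir: str | Path,
    cohort: CohortBundle,
    metabolites: pd.DataFrame | None = None,
    behavior: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the cohort (and optional companion tables) as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {"subjects": cohort.subjects, "thickness": cohort.thickness}
    if metabolites is not None:
        tables["metabolites"] = metabolites
    if behavior is not None:
        tables["behavior"] = behavior
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", float_format="%.10g")
        paths[name] = path
    return paths
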