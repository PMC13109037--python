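"""Covariate correction and normative z-scoring of regional thickness.

Raw regional thickness is residualized against age, sex, education and
global mean cortical thickness by per-region ordinary least squares. The
regression is fitted on the healthy-control group only (normative-model
convention) and the fitted coefficients are applied to every subject; each
region's residuals are then standardized with the control-group mean and
sample standard deviation, so a z-score expresses a subject's deviation from
the healthy reference in reference-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COVARIATE_COLUMNS, CohortBundle


@dataclass
class ZScoreMatrix:
    """Standardized residual deviations plus the reference statistics.

    ``z`` is subjects x regions; ``reference_mean`` / ``reference_sd`` hold
    the per-region residual mean and sample SD of the reference group used
    for standardization.
    """

    z: pd.DataFrame
    reference_mean: pd.Series
    reference_sd: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.reference_sd.to_numpy() <= 0):
            bad = self.reference_sd.index[self.reference_sd <= 0]
            raise ValueError(f"non-positive reference SD for regions {list(bad)}")

    @property
    def regions(self) -> list[str]:
        return list(self.z.columns)


def load_thickness_table(path: str | Path, covariate_path: str | Path) -> CohortBundle:
    """Read thickness and covariate TSV tables into a validated bundle.

    Both tables must carry a ``subject_id`` column (or index); ids must match
    one-to-one. ``global_mean_thickness`` is computed from the thickness rows
    when the covariate table lacks it.
    """
    path, covariate_path = Path(path), Path(covariate_path)
    for p in (path, covariate_path):
        if not p.exists():
            raise FileNotFoundError(p)
    thickness = pd.read_csv(path, sep="\t", index_col="subject_id")
    subjects = pd.read_csv(covariate_path, sep="\t", index_col="subject_id")

    non_numeric = [
        c for c in thickness.columns if not pd.api.types.is_numeric_dtype(thickness[c])
    ]
    if non_numeric:
        raise ValueError(f"non-numeric thickness columns: {non_numeric}")
    for frame, name in ((thickness, path), (subjects, covariate_path)):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique()
            raise ValueError(f"duplicate subject ids in {name}: {list(dupes)}")
    only_thick = thickness.index.difference(subjects.index)
    only_cov = subjects.index.difference(thickness.index)
    if len(only_thick) or len(only_cov):
        raise ValueError(
            "subject ids do not align across files; "
            f"thickness-only: {list(only_thick)}, covariates-only: {list(only_cov)}"
        )
    missing = [c for c in ("group", "age", "sex", "education") if c not in subjects.columns]
    if missing:
        raise ValueError(f"covariate table lacks required columns: {missing}")
    thickness = thickness.loc[subjects.index]
    row_means = thickness.to_numpy(dtype=float).mean(axis=1)
    if "global_mean_thickness" in subjects.columns:
        # stored column may carry serialization rounding; accept small
        # deviations and keep the exact row mean
        stored = subjects["global_mean_thickness"].to_numpy(dtype=float)
        if np.max(np.abs(stored - row_means)) > 1e-6:
            raise ValueError(
                "global_mean_thickness column disagrees with the thickness row means"
            )
    subjects = subjects.assign(global_mean_thickness=row_means)
    return CohortBundle(subjects, thickness)


def average_hemispheres(thickness: pd.DataFrame) -> pd.DataFrame:
    """Collapse 68 hemispheric columns (``lh_*``/``rh_*``) to 34 homologue means."""
    lh = sorted(c for c in thickness.columns if c.startswith("lh_"))
    rh = sorted(c for c in thickness.columns if c.startswith("rh_"))
    base_l = [c[3:] for c in lh]
    base_r = [c[3:] for c in rh]
    if not lh or base_l != base_r:
        raise ValueError("expected matching lh_/rh_ column pairs")
    out = {
        base: (thickness[f"lh_{base}"] + thickness[f"rh_{base}"]) / 2.0
        for base in base_l
    }
    return pd.DataFrame(out, index=thickness.index)


def residualize_thickness(
    bundle: CohortBundle,
    fit_group: str | None = "HC",
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """Per-region OLS residuals of thickness on the covariates.

    The design is ``[intercept] + covariates``, fitted on ``fit_group``
    subjects (``None`` fits on everyone) and applied to all rows. Constant or
    otherwise collinear covariates within the fit group are rejected so the
    coefficients stay identifiable.
    """
    cov = bundle.subjects
    missing = [c for c in covariates if c not in cov.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    X_all = np.column_stack(
        [np.ones(bundle.n_subjects)] + [cov[c].to_numpy(dtype=float) for c in covariates]
    )
    if not np.all(np.isfinite(X_all)):
        raise ValueError("covariates contain missing or non-finite values")
    fit_mask = (
        np.ones(bundle.n_subjects, dtype=bool)
        if fit_group is None
        else (cov["group"] == fit_group).to_numpy()
    )
    if not fit_mask.any():
        raise ValueError(f"fit group {fit_group!r} selects no subjects")
    X_fit = X_all[fit_mask]
    if X_fit.shape[0] <= X_fit.shape[1]:
        raise ValueError(
            f"fit group has {X_fit.shape[0]} subjects for {X_fit.shape[1]} regressors"
        )
    for j, name in enumerate(covariates, start=1):
        if np.ptp(X_fit[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant within the fit group")
    if np.linalg.matrix_rank(X_fit) < X_fit.shape[1]:
        raise ValueError("covariate design is rank-deficient (collinear covariates)")

    Y = bundle.thickness.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X_fit, Y[fit_mask], rcond=None)
    residuals = Y - X_all @ beta
    return pd.DataFrame(residuals, index=bundle.thickness.index, columns=bundle.thickness.columns)


def zscore_to_reference(residuals: pd.DataFrame, hc_mask: np.ndarray) -> ZScoreMatrix:
    """Standardize residuals with reference-group mean and sample SD (ddof=1)."""
    hc_mask = np.asarray(hc_mask, dtype=bool)
    if hc_mask.shape != (len(residuals),):
        raise ValueError("hc_mask length does not match the residual matrix")
    if hc_mask.sum() < 3:
        raise ValueError("need at least 3 reference subjects for z-scoring")
    ref = residuals.iloc[hc_mask]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    if np.any(sd.to_numpy() <= 0):
        bad = sd.index[sd <= 0]
        raise ValueError(f"zero reference SD for regions {list(bad)}")
    z = (residuals - mean) / sd
    return ZScoreMatrix(z=z, reference_mean=mean, reference_sd=sd)


def prepare_zscores(
    bundle: CohortBundle,
    fit_group: str | None = "HC",
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
) -> ZScoreMatrix:
    """Residualize then z-score against the healthy-control reference."""
    residuals = residualize_thickness(bundle, fit_group=fit_group, covariates=covariates)
    return zscore_to_reference(residuals, bundle.hc_mask())
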