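"""Per-region volumetric sex effects.

Region volumes and total tissue volume (TTV) are z-scored across all
subjects (both sexes pooled, sample SD), then each region is modelled by
ordinary least squares:

    volume_z ~ intercept + b1·sex + b2·age + b3·ttv_z [+ b4·batch / qc]

with sex coded female = 0, male = 1, so positive b1 means a male-biased
regional volume. Two-sided p-values for b1 come from the t distribution
and are BH-FDR corrected across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CohortTable
from .sexdiff import fdr_bh

#: covariate sets per species profile
PROFILE_COVARIATES = {
    "mouse_like": ("age", "ttv", "batch"),
    "human_like": ("age", "ttv", "qc_covariate"),
}


def zscore_columns(cohort: CohortTable) -> CohortTable:
    """Z-score every region volume and TTV across all subjects (sample SD,
    n−1 denominator); other covariates untouched."""
    out = cohort.copy()
    sds = out.volumes.std(axis=0, ddof=1)
    dead = list(sds.index[sds == 0])
    if dead:
        raise ValidationError(f"zero-variance region columns: {dead}")
    out.volumes = (out.volumes - out.volumes.mean(axis=0)) / sds
    ttv = out.subjects["ttv"]
    tsd = float(ttv.std(ddof=1))
    if tsd == 0:
        raise ValidationError("zero-variance ttv column")
    out.subjects["ttv"] = (ttv - ttv.mean()) / tsd
    return out


def _design_matrix(cohort: CohortTable, covariates,
                   sex_code: dict[str, float] | None = None,
                   ) -> tuple[np.ndarray, list[str]]:
    sex_code = sex_code or {"female": 0.0, "male": 1.0}
    n = cohort.n_subjects
    cols = [np.ones(n), cohort.sex.map(sex_code).to_numpy(dtype=float)]
    names = ["intercept", "sex"]
    for cov in covariates:
        if cov == "batch":
            batch = cohort.subjects["batch"].astype(str)
            levels = sorted(batch.unique())
            for lev in levels[1:]:  # first (lexicographic) level = reference
                cols.append((batch == lev).to_numpy(dtype=float))
                names.append(f"batch[{lev}]")
        elif cov in ("age", "ttv", "qc_covariate"):
            if cov not in cohort.subjects.columns:
                raise ValidationError(f"covariate {cov!r} absent from cohort")
            v = cohort.subjects[cov].to_numpy(dtype=float)
            cols.append(v - v.mean())  # centered; affects only the intercept
            names.append(cov)
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), names


@dataclass
class VolumetricEffects:
    """Per-region standardized sex coefficients with FDR across regions."""

    table: pd.DataFrame  # index region_id; beta1, se, t, p, q, sex_biased
    covariates: tuple[str, ...]

    @property
    def beta1(self) -> pd.Series:
        return self.table["beta1"]

    def biased_regions(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["sex_biased"] == direction])


def volumetric_sex_effects(cohort: CohortTable,
                           covariates=("age", "ttv", "batch"),
                           q_threshold: float = 0.05,
                           sex_code: dict[str, float] | None = None,
                           ) -> VolumetricEffects:
    """Fit the covariate-adjusted sex-effect model for every region.

    Expects a z-scored cohort (see :func:`zscore_columns`). All regions
    share one design matrix, so the fit is a single multi-response least
    squares; standard errors use the per-region residual variance and
    the shared (X'X)⁻¹.
    """
    x, names = _design_matrix(cohort, covariates, sex_code)
    n, k = x.shape
    if n <= k:
        raise ValidationError("more design columns than subjects")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {k}); columns: {names}"
        )
    y = cohort.volumes.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)                 # k × p
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - k)  # per region
    se1 = np.sqrt(sigma2 * xtx_inv[1, 1])
    b1 = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se1 > 0, b1 / se1, 0.0)
    p = 2 * stats.t.sf(np.abs(t), n - k)
    q, sig = fdr_bh(p, q_threshold)
    label = np.where(~sig, "none", np.where(b1 > 0, "male", "female"))
    table = pd.DataFrame(
        {"beta1": b1, "se": se1, "t": t, "p": p, "q": q, "sex_biased": label},
        index=pd.Index(cohort.region_ids, name="region_id"),
    )
    return VolumetricEffects(table=table, covariates=tuple(covariates))
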