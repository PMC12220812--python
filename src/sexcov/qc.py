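"""Subject-level quality control and preprocessing.

Three stages feed the covariance analysis, in the order they are run by
the pipeline: a QC-covariate threshold filter (e.g. excluding scans with
Euler numbers below a cutoff), a maximal-Cook's-distance influence
screen over all pairwise inter-regional regressions, simplified
location-scale batch adjustment, and within-sex age residualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MIN_PER_SEX, CohortTable

log = logging.getLogger(__name__)

#: flag a subject whose maximal Cook's distance lies more than this many
#: z-scores above the cohort mean of maxima
COOKS_Z_CUTOFF = 3.0


# ---------------------------------------------------------------------------
# threshold filter
# ---------------------------------------------------------------------------

def qc_threshold_filter(cohort: CohortTable, covariate_name: str,
                        threshold: float, direction: str = "min",
                        min_per_sex: int = MIN_PER_SEX,
                        ) -> tuple[CohortTable, list[str]]:
    """Exclude subjects failing a numeric QC threshold.

    ``direction="min"`` excludes subjects with covariate strictly below
    the threshold (the Euler-number convention: values less than the
    cutoff are excluded); ``direction="max"`` excludes values strictly
    above it.
    """
    if covariate_name not in cohort.subjects.columns:
        raise ValidationError(f"covariate {covariate_name!r} absent from cohort")
    values = pd.to_numeric(cohort.subjects[covariate_name])
    if direction == "min":
        fail = values < threshold
    elif direction == "max":
        fail = values > threshold
    else:
        raise ValidationError("direction must be 'min' or 'max'")
    excluded = list(cohort.subjects.index[fail])
    kept_sex = cohort.subjects.loc[~fail, "sex"]
    counts = {s: int((kept_sex == s).sum()) for s in ("female", "male")}
    if min(counts.values()) < min_per_sex:
        raise ValidationError(
            f"filter leaves {counts}; inclusion rule requires at least "
            f"{min_per_sex} subjects per sex"
        )
    kept = cohort.subset_subjects(cohort.subjects.index[~fail])
    if excluded:
        log.info("qc_threshold_filter excluded %d subjects: %s",
                 len(excluded), excluded)
    return kept, excluded


# ---------------------------------------------------------------------------
# Cook's-distance outlier screen
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Per-subject maximal Cook's distance over all pairwise regressions."""

    table: pd.DataFrame  # index subject_id; max_cooks, z_max_cooks, flagged

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def flag_outliers_cooks(cohort: CohortTable) -> OutlierReport:
    """Screen subjects unusually influential on any pairwise volume relation.

    For every ordered region pair (y, x) a simple least-squares line
    ``y = a + b·x`` is fitted on the mixed-sex cohort; each subject's
    Cook's distance ``D_i = e_i² h_ii / (k s² (1-h_ii)²)`` with k = 2
    parameters is computed, and the subject's maximum over all models is
    recorded. Maxima are z-scored across subjects; z > 3 flags a subject.
    """
    vols = cohort.volumes.to_numpy(dtype=float)
    n, p = vols.shape
    if n < 3:
        raise ValidationError("Cook's screen needs at least 3 subjects")
    if p < 2:
        raise ValidationError("Cook's screen needs at least 2 regions")

    max_d = np.zeros(n)
    used_any = False
    k = 2  # intercept + slope
    for xj in range(p):
        x = vols[:, xj]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx <= 0:
            log.warning("region %s has zero variance; pairs with it as "
                        "predictor skipped", cohort.region_ids[xj])
            continue
        used_any = True
        h = 1.0 / n + xc**2 / sxx                      # leverage, shared by all y
        ys = np.delete(vols, xj, axis=1)
        yc = ys - ys.mean(axis=0)
        b = (xc @ yc) / sxx                            # slopes, one per response
        resid = yc - np.outer(xc, b)
        s2 = (resid**2).sum(axis=0) / (n - k)          # per-response sigma^2
        syy = (yc**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = resid**2 * h[:, None] / (k * s2[None, :] * (1.0 - h[:, None])**2)
        # an (exactly) collinear pair has residuals at rounding level:
        # Cook's distance is 0/0 there and the model carries no influence
        # information, so it contributes zero
        perfect = s2 <= 1e-20 * np.where(syy > 0, syy, 1.0)
        d = np.where(perfect[None, :], 0.0, d)
        np.maximum(max_d, d.max(axis=1), out=max_d)
    if not used_any:
        raise ValidationError("all region pairs skipped (zero-variance regions)")

    sd = max_d.std(ddof=1)
    if sd == 0:
        z = np.zeros(n)
    else:
        z = (max_d - max_d.mean()) / sd
    table = pd.DataFrame(
        {"max_cooks": max_d, "z_max_cooks": z, "flagged": z > COOKS_Z_CUTOFF},
        index=cohort.subjects.index,
    )
    return OutlierReport(table=table)


def remove_flagged(cohort: CohortTable, report: OutlierReport,
                   min_per_sex: int = MIN_PER_SEX) -> tuple[CohortTable, list[str]]:
    """Opt-in removal of Cook's-flagged subjects (default pipeline keeps
    them, flag-only, since visual review cannot be automated)."""
    removed = report.flagged_ids
    kept = cohort.subset_subjects(
        [s for s in cohort.subjects.index if s not in set(removed)]
    )
    kept.check_min_per_sex(min_per_sex)
    return kept, removed


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------

def batch_adjust(cohort: CohortTable, method: str = "location_scale",
                 ) -> CohortTable:
    """Simplified batch harmonization of the region volumes.

    ``center``: per region and batch, subtract the batch mean and add the
    grand mean (removes additive offsets exactly).
    ``location_scale``: additionally rescale each batch's SD to the
    pooled (batch-centered) SD. ``none``: identity.

    This is a moment-matching stand-in for empirical-Bayes harmonization:
    no shrinkage across regions and no covariate protection. TTV is
    recomputed as the row-sum of the adjusted volumes.
    """
    if method == "none":
        return cohort.copy()
    if method not in ("center", "location_scale"):
        raise ValidationError(f"unknown batch adjustment method {method!r}")
    if "batch" not in cohort.subjects.columns:
        raise ValidationError("batch column absent from cohort")
    batches = cohort.subjects["batch"]
    counts = batches.value_counts()
    if method == "location_scale" and (counts < 2).any():
        singles = list(counts.index[counts < 2])
        raise ValidationError(
            f"location_scale undefined for singleton batches: {singles}"
        )

    out = cohort.copy()
    if batches.nunique() == 1:
        return out
    vols = out.volumes
    grand_mean = vols.mean(axis=0)
    batch_mean = vols.groupby(batches).transform("mean")
    centered = vols - batch_mean
    if method == "center":
        adjusted = centered + grand_mean
    else:
        pooled_sd = centered.std(axis=0, ddof=1)
        batch_sd = vols.groupby(batches).transform(lambda s: s.std(ddof=1))
        adjusted = centered / batch_sd * pooled_sd + grand_mean
    out.volumes = adjusted
    out.subjects["ttv"] = adjusted.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# within-sex age residualization
# ---------------------------------------------------------------------------

@dataclass
class ResidualTable:
    """Residuals of volume on age, fitted separately within each sex."""

    residuals: pd.DataFrame  # subjects × regions
    sex: pd.Series
    age: pd.Series

    @property
    def region_ids(self) -> list[str]:
        return list(self.residuals.columns)


def residualize_groups(vols: np.ndarray, age: np.ndarray,
                       is_male: np.ndarray) -> np.ndarray:
    """OLS residuals of each volume column on [1, age], fitted separately
    in the two label groups. Core kernel shared with the permutation
    engine, hence plain ndarrays."""
    resid = np.empty_like(vols)
    for mask in (~is_male, is_male):
        a = age[mask]
        if np.ptp(a) == 0:
            raise ValidationError(
                "age is constant within a sex group; disable age "
                "residualization for this cohort"
            )
        x = np.column_stack([np.ones(mask.sum()), a])
        coef, *_ = np.linalg.lstsq(x, vols[mask], rcond=None)
        resid[mask] = vols[mask] - x @ coef
    return resid


def residualize_age(cohort: CohortTable) -> ResidualTable:
    """Regress age out of every region volume, separately per sex.

    Residuals (not fitted values) feed all downstream correlation
    analyses; the sexes are never pooled in this fit.
    """
    vols = cohort.volumes.to_numpy(dtype=float)
    age = cohort.subjects["age"].to_numpy(dtype=float)
    is_male = (cohort.sex == "male").to_numpy()
    resid = residualize_groups(vols, age, is_male)
    return ResidualTable(
        residuals=pd.DataFrame(resid, index=cohort.volumes.index,
                               columns=cohort.volumes.columns),
        sex=cohort.sex.copy(),
        age=cohort.subjects["age"].copy(),
    )
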