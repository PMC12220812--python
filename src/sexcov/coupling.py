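"""Regional covariance-bias summaries and their coupling with volumetric
sex effects.

The edge-level difference matrix D is collapsed to per-region means
(signed and absolute; over all incident edges and over the FDR-significant
subset). The brain-wide coupling test correlates the regional covariance
bias with the per-region volumetric sex coefficient b1 and assesses it
against a null of sex-label permutations in which *both* arms — the
covariance differences and the volumetric model — are recomputed per
iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CohortTable, RegionMeta
from .qc import residualize_groups
from .sexdiff import SexDiffResult, _cohort_arrays, _corr, _sign_factor
from .volumetrics import VolumetricEffects, zscore_columns


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------

def regional_mean_bias(sexdiff: SexDiffResult) -> pd.DataFrame:
    """Per-region mean covariance sex difference.

    For each region: the mean of D over its p−1 incident edges (signed
    and absolute), and the same restricted to FDR-significant incident
    edges (NaN when the region has none).
    """
    regions = sexdiff.region_ids
    edges = sexdiff.edges
    rows = []
    for region in regions:
        inc = edges[(edges["region_i"] == region) | (edges["region_j"] == region)]
        d = inc["D"].to_numpy()
        sig = inc[inc["significant"]]
        ds = sig["D"].to_numpy()
        rows.append({
            "region_id": region,
            "mean_signed_all": float(d.mean()),
            "mean_abs_all": float(np.abs(d).mean()),
            "mean_signed_sig": float(ds.mean()) if len(ds) else np.nan,
            "mean_abs_sig": float(np.abs(ds).mean()) if len(ds) else np.nan,
            "n_sig_edges": int(len(ds)),
        })
    return pd.DataFrame(rows).set_index("region_id")


def female_biased_region_fraction(regional: pd.DataFrame,
                                  column: str = "mean_signed_all",
                                  sign_convention: str = "male_minus_female",
                                  ) -> float:
    """Fraction of regions whose mean signed bias is female-biased
    (negative under male_minus_female), among regions with a defined
    value in the chosen column."""
    sign = _sign_factor(sign_convention)
    vals = sign * regional[column].dropna()
    if len(vals) == 0:
        return float("nan")
    return float((vals < 0).mean())


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------

def coupling_correlation(regional: pd.DataFrame, effects: VolumetricEffects,
                         mode: str = "signed",
                         column: str | None = None) -> float:
    """Pearson correlation between regional covariance bias and b1.

    ``signed``: mean_signed_all vs b1. ``absolute``: mean_abs_all vs
    |b1|. Zero variance in either vector yields NaN with a warning, never
    a silent 0.
    """
    if set(regional.index) != set(effects.table.index):
        raise ValidationError("region sets differ between bias and effects")
    eff = effects.table.loc[regional.index]
    if mode == "signed":
        x = regional[column or "mean_signed_all"].to_numpy(dtype=float)
        y = eff["beta1"].to_numpy(dtype=float)
    elif mode == "absolute":
        x = regional[column or "mean_abs_all"].to_numpy(dtype=float)
        y = np.abs(eff["beta1"].to_numpy(dtype=float))
    else:
        raise ValidationError(f"unknown coupling mode {mode!r}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("coupling correlation needs >= 3 regions")
    if _degenerate(x) or _degenerate(y):
        warnings.warn("zero variance in a coupling arm; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def _degenerate(v: np.ndarray) -> bool:
    """Constant up to rounding (a constant D field collapses to regional
    means that differ only in the last bit)."""
    return float(np.ptp(v)) <= 1e-12 * max(1.0, float(np.abs(v).max()))


@dataclass
class CouplingResult:
    r_obs: float
    p_perm: float
    mode: str
    n_perm: int
    n_regions: int
    seed: int


def _coupling_arms(vols_raw: np.ndarray, volz: np.ndarray, age: np.ndarray,
                   is_male: np.ndarray, x_design: np.ndarray,
                   sign: float, mode: str, region_ids) -> float:
    """One evaluation of the coupling correlation from raw arrays.

    Arm 1: within-group age residualization of raw volumes -> per-group
    correlation matrices -> D -> all-pairs regional means.
    Arm 2: multi-response OLS of z-scored volumes on the design whose sex
    column is given by ``is_male`` -> b1 per region.
    """
    res = residualize_groups(vols_raw, age, is_male)
    rf = _corr(res[~is_male], region_ids, "female")
    rm = _corr(res[is_male], region_ids, "male")
    d = sign * (rm - rf)
    np.fill_diagonal(d, 0.0)
    p = d.shape[0]
    # zero diagonal contributes 0 to both sums; dividing by p-1 gives the
    # mean over incident edges
    regional = d.sum(axis=1) / (p - 1)
    regional_abs = np.abs(d).sum(axis=1) / (p - 1)

    x = x_design.copy()
    x[:, 1] = is_male.astype(float)
    beta = np.linalg.solve(x.T @ x, x.T @ volz)
    b1 = beta[1]

    if mode == "signed":
        a, b = regional, b1
    else:
        a, b = regional_abs, np.abs(b1)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def coupling_permutation_test(cohort: CohortTable, mode: str = "signed",
                              n_perm: int = 1000, seed: int = 0,
                              covariates=("age", "ttv", "batch"),
                              sign_convention: str = "male_minus_female",
                              ) -> CouplingResult:
    """Permutation test of the covariance-bias / volumetric-bias coupling.

    Each iteration permutes the sex labels once and recomputes both arms
    (within-group residualization → D → all-pairs regional means; and the
    per-region sex-effect model with the permuted sex column) before
    correlating them; p = (1 + #{|null r| >= |r_obs|}) / (n_perm + 1).

    The all-pairs regional means are used inside the null (the
    significant-edge subset is undefined within a null iteration without
    nesting the full edge-wise permutation).
    """
    if mode not in ("signed", "absolute"):
        raise ValidationError(f"unknown coupling mode {mode!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    from .volumetrics import _design_matrix

    order, vols, age, is_male = _cohort_arrays(cohort)
    sign = _sign_factor(sign_convention)
    zc = zscore_columns(cohort)
    volz = zc.volumes[order].to_numpy(dtype=float)
    # design matrix built once; the sex column is overwritten per iteration
    x_design, _ = _design_matrix(zc, covariates)

    r_obs = _coupling_arms(vols, volz, age, is_male, x_design, sign, mode, order)
    if np.isnan(r_obs):
        raise ValidationError("observed coupling correlation is undefined "
                              "(zero variance in an arm)")
    children = np.random.SeedSequence(seed).spawn(n_perm)
    count = 0
    n = len(age)
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        labels = is_male[rng.permutation(n)]
        try:
            r_null = _coupling_arms(vols, volz, age, labels, x_design, sign,
                                    mode, order)
        except ValidationError as exc:
            raise ValidationError(f"coupling iteration {it} failed: {exc}") from exc
        if not np.isnan(r_null) and abs(r_null) >= abs(r_obs):
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return CouplingResult(r_obs=r_obs, p_perm=p, mode=mode, n_perm=n_perm,
                          n_regions=len(order), seed=seed)


# ---------------------------------------------------------------------------
# hemispheric symmetry
# ---------------------------------------------------------------------------

def hemispheric_symmetry(regional: pd.DataFrame, meta: RegionMeta,
                         column: str = "mean_signed_all",
                         ) -> tuple[float, int]:
    """Pearson correlation of a regional bias column between left regions
    and their right homotopic partners. Midline and unpaired regions are
    excluded; returns (r, n_pairs)."""
    if column not in regional.columns:
        raise ValidationError(f"unknown bias column {column!r}")
    left_vals, right_vals = [], []
    for left, right in meta.homotopic_pairs():
        if left not in regional.index or right not in regional.index:
            continue
        lv = regional.loc[left, column]
        rv = regional.loc[right, column]
        if np.isnan(lv) or np.isnan(rv):
            continue
        left_vals.append(float(lv))
        right_vals.append(float(rv))
    if len(left_vals) < 3:
        raise ValidationError(
            f"hemispheric symmetry needs >= 3 usable homotopic pairs, "
            f"got {len(left_vals)}"
        )
    r = float(stats.pearsonr(left_vals, right_vals)[0])
    return r, len(left_vals)
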