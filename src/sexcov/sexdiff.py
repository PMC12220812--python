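"""Edge-wise sex differences in inter-regional volume correlation.

The core procedure: within each sex, Pearson-correlate the age-residualized
region volumes across subjects to obtain per-sex correlation matrices;
take the signed per-edge difference D under a configurable sign
convention; build a null by permuting sex labels across subjects and
re-running the whole process (including the within-group age
residualization) for each iteration; convert to two-sided empirical
p-values with add-one smoothing; and control the false discovery rate
across edges with Benjamini–Hochberg at q < 0.05.

Sign convention: under the default ``male_minus_female``, positive D
means the male correlation is larger (male-biased covariance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CohortTable, canonical_pairs
from .qc import ResidualTable, residualize_groups

SIGN_CONVENTIONS = ("male_minus_female", "female_minus_male")


def _sign_factor(sign_convention: str) -> float:
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValidationError(f"unknown sign convention {sign_convention!r}")
    return 1.0 if sign_convention == "male_minus_female" else -1.0


# ---------------------------------------------------------------------------
# correlation matrices and the difference matrix
# ---------------------------------------------------------------------------

def _corr(mat: np.ndarray, region_ids, sex_name: str) -> np.ndarray:
    sds = mat.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        names = [region_ids[i] for i in dead]
        raise ValidationError(
            f"zero-variance regions within {sex_name}: {names}"
        )
    r = np.corrcoef(mat, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def sex_correlation_matrices(residuals: ResidualTable,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sex Pearson correlation matrices of the residual columns.

    Regions are returned in canonical (lexicographic) order so that the
    upper triangle enumerates the canonical edge order.
    """
    order = sorted(residuals.region_ids)
    res = residuals.residuals[order]
    out = []
    for sex_name in ("female", "male"):
        mask = (residuals.sex == sex_name).to_numpy()
        if mask.sum() < 3:
            raise ValidationError(f"need >= 3 {sex_name} subjects")
        r = _corr(res.to_numpy(dtype=float)[mask], order, sex_name)
        out.append(pd.DataFrame(r, index=order, columns=order))
    return out[0], out[1]


def sexdiff_matrix(r_female: pd.DataFrame, r_male: pd.DataFrame,
                   sign_convention: str = "male_minus_female") -> pd.DataFrame:
    """Signed per-edge correlation difference matrix D."""
    if r_female.shape != r_male.shape or list(r_female.columns) != list(r_male.columns):
        raise ValidationError("correlation matrices are not conformable")
    s = _sign_factor(sign_convention)
    d = s * (r_male.to_numpy() - r_female.to_numpy())
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=r_female.index, columns=r_female.columns)


def edge_vector(matrix: pd.DataFrame) -> np.ndarray:
    """Upper-triangle values in canonical edge order (requires the matrix
    columns to already be in canonical order)."""
    m = matrix.to_numpy()
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _cohort_arrays(cohort: CohortTable):
    order = sorted(cohort.region_ids)
    vols = cohort.volumes[order].to_numpy(dtype=float)
    age = cohort.subjects["age"].to_numpy(dtype=float)
    is_male = (cohort.sex == "male").to_numpy()
    return order, vols, age, is_male


def _edge_d(vols: np.ndarray, age: np.ndarray, is_male: np.ndarray,
            sign: float, region_ids, residualize: bool = True,
            ) -> np.ndarray:
    if residualize:
        res = residualize_groups(vols, age, is_male)
    else:
        res = vols
    rf = _corr(res[~is_male], region_ids, "female")
    rm = _corr(res[is_male], region_ids, "male")
    iu = np.triu_indices(res.shape[1], 1)
    return sign * (rm[iu] - rf[iu])


def permutation_null(cohort: CohortTable, n_perm: int, seed: int = 0,
                     sign_convention: str = "male_minus_female",
                     mode: str = "full") -> np.ndarray:
    """Null distribution of the edge-wise difference D under label
    permutation.

    Each iteration permutes the sex labels across subjects (group sizes
    preserved), re-runs the within-group age residualization on the
    permuted groups (``mode="full"``, the default, literal re-run of the
    whole process) or reuses the observed-group residuals and permutes
    only their labels (``mode="fast"``), recomputes both correlation
    matrices and D. Returns an (n_perm, n_edges) array.

    One master seed spawns per-iteration substreams, so results do not
    depend on any parallelization granularity.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if mode not in ("full", "fast"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    order, vols, age, is_male = _cohort_arrays(cohort)
    sign = _sign_factor(sign_convention)
    n = len(age)
    if mode == "fast":
        base = residualize_groups(vols, age, is_male)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    n_edges = len(order) * (len(order) - 1) // 2
    null = np.empty((n_perm, n_edges))
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.permutation(n)
        labels = is_male[idx]
        try:
            if mode == "full":
                null[it] = _edge_d(vols, age, labels, sign, order,
                                   residualize=True)
            else:
                null[it] = _edge_d(base, age, labels, sign, order,
                                   residualize=False)
        except ValidationError as exc:
            raise ValidationError(
                f"permutation iteration {it} failed: {exc}"
            ) from exc
    return null


def exhaustive_null(cohort: CohortTable,
                    sign_convention: str = "male_minus_female",
                    mode: str = "full") -> np.ndarray:
    """Null D over *all* label assignments preserving group sizes.

    Feasible only for tiny cohorts (C(n, n_female) assignments); used as
    an enumeration oracle for the Monte-Carlo permutation null.
    """
    order, vols, age, is_male = _cohort_arrays(cohort)
    sign = _sign_factor(sign_convention)
    n = len(age)
    n_male = int(is_male.sum())
    base = residualize_groups(vols, age, is_male) if mode == "fast" else None
    rows = []
    for male_set in itertools.combinations(range(n), n_male):
        labels = np.zeros(n, dtype=bool)
        labels[list(male_set)] = True
        if mode == "full":
            rows.append(_edge_d(vols, age, labels, sign, order, True))
        else:
            rows.append(_edge_d(base, age, labels, sign, order, False))
    return np.asarray(rows)


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Two-sided empirical p with add-one smoothing:
    p = (1 + #{|null| >= |obs|}) / (n_perm + 1), per edge."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[1] != observed.shape[0]:
        raise ValidationError("null stack shape does not match observed D")
    count = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    return (1.0 + count) / (null.shape[0] + 1.0)


def fdr_bh(p: np.ndarray, q_threshold: float = 0.05,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and a q < threshold mask."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


# ---------------------------------------------------------------------------
# assembled edge-wise result
# ---------------------------------------------------------------------------

@dataclass
class SexDiffResult:
    """Edge-wise per-sex correlations, signed difference, permutation p,
    BH q and significance mask, on canonical edges."""

    edges: pd.DataFrame  # region_i, region_j, r_female, r_male, D, p_perm, q, significant
    r_female: pd.DataFrame
    r_male: pd.DataFrame
    sign_convention: str
    n_perm: int
    seed: int
    q_threshold: float

    @property
    def region_ids(self) -> list[str]:
        return list(self.r_female.columns)

    @property
    def n_significant(self) -> int:
        return int(self.edges["significant"].sum())

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


def run_sexdiff(cohort: CohortTable, n_perm: int = 1000, seed: int = 0,
                sign_convention: str = "male_minus_female",
                q_threshold: float = 0.05, mode: str = "full",
                null: np.ndarray | None = None) -> SexDiffResult:
    """Full edge-wise analysis on an already QC'd, batch-adjusted cohort.

    A precomputed ``null`` stack (e.g. from :func:`exhaustive_null`) can
    be supplied; otherwise ``n_perm`` label permutations are drawn.
    """
    from .qc import residualize_age

    residuals = residualize_age(cohort)
    r_f, r_m = sex_correlation_matrices(residuals)
    d_mat = sexdiff_matrix(r_f, r_m, sign_convention)
    observed = edge_vector(d_mat)
    if null is None:
        null = permutation_null(cohort, n_perm, seed, sign_convention, mode)
    p = empirical_pvalues(observed, null)
    q, sig = fdr_bh(p, q_threshold)
    pairs = canonical_pairs(cohort.region_ids)
    edges = pd.DataFrame({
        "region_i": [a for a, _ in pairs],
        "region_j": [b for _, b in pairs],
        "r_female": edge_vector(r_f),
        "r_male": edge_vector(r_m),
        "D": observed,
        "p_perm": p,
        "q": q,
        "significant": sig,
    })
    return SexDiffResult(edges=edges, r_female=r_f, r_male=r_m,
                         sign_convention=sign_convention,
                         n_perm=null.shape[0], seed=seed,
                         q_threshold=q_threshold)


# ---------------------------------------------------------------------------
# mean-correlation comparison and strength-vs-difference
# ---------------------------------------------------------------------------

@dataclass
class MeanComparison:
    """Paired comparison of mean per-edge correlations between the sexes."""

    mean_female: float
    mean_male: float
    delta: float          # on the configured sign convention
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    n_edges: int
    edge_subset: str
    degenerate: bool = False


def compare_mean_correlations(r_female: pd.DataFrame, r_male: pd.DataFrame,
                              edge_mask: np.ndarray | None = None,
                              sign_convention: str = "male_minus_female",
                              edge_subset: str = "all") -> MeanComparison:
    """Paired t-test of the per-edge correlations between sexes.

    Edges are matched between the sexes (the same region pair), so the
    test is paired across edges. Raw correlations are compared, no
    Fisher z-transform.
    """
    sign = _sign_factor(sign_convention)
    rf = edge_vector(r_female)
    rm = edge_vector(r_male)
    if edge_mask is not None:
        mask = np.asarray(edge_mask, dtype=bool)
        rf, rm = rf[mask], rm[mask]
    if rf.size < 2:
        raise ValidationError("mean comparison needs >= 2 selected edges")
    diffs = sign * (rm - rf)
    delta = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    n = diffs.size
    if sd == 0:
        return MeanComparison(float(rf.mean()), float(rm.mean()), delta,
                              delta, delta, 0.0, n - 1, n, edge_subset,
                              degenerate=True)
    se = sd / np.sqrt(n)
    t_stat = delta / se
    half = stats.t.ppf(0.975, n - 1) * se
    return MeanComparison(float(rf.mean()), float(rm.mean()), delta,
                          delta - half, delta + half, float(t_stat),
                          n - 1, n, edge_subset)


def strength_vs_difference(r_female: pd.DataFrame, r_male: pd.DataFrame,
                           d: np.ndarray, p: np.ndarray,
                           thresholds: list[float]) -> pd.DataFrame:
    """Relationship of within-sex covariance strength to |D| at a series
    of significance thresholds.

    For each threshold t, restricts to edges with p <= t and Pearson-
    correlates the mean within-sex strength (r_f + r_m)/2 with |D|.
    Thresholds retaining fewer than 3 edges are reported as undefined
    (NaN), not errors.
    """
    for t in thresholds:
        if not (0 < t <= 1):
            raise ValidationError("thresholds must lie in (0, 1]")
    strength = 0.5 * (edge_vector(r_female) + edge_vector(r_male))
    absd = np.abs(np.asarray(d, dtype=float))
    p = np.asarray(p, dtype=float)
    rows = []
    for t in thresholds:
        keep = p <= t
        n_edges = int(keep.sum())
        if n_edges < 3 or strength[keep].std() == 0 or absd[keep].std() == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(strength[keep], absd[keep])[0])
        rows.append({"threshold": t, "n_edges": n_edges,
                     "strength_absdiff_r": r})
    return pd.DataFrame(rows)
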