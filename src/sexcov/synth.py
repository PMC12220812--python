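"""Synthetic cohorts with planted sex-specific covariance structure.

The generator draws each sex from a multivariate normal whose population
correlation matrix is an exchangeable (or block) base matrix perturbed on
a configurable set of "planted" edges: for a planted edge with difference
``delta`` (female minus male), the female matrix gets ``rho0 + delta/2``
and the male matrix ``rho0 - delta/2``, so the pooled correlation stays
at the base value and ``delta`` is the exact population analogue of the
edge-wise sex-difference statistic downstream.

Volumetric sex effects are planted as mean shifts in units of the
region's within-sex SD (male minus female, split symmetrically about the
common mean). Age acts through per-region slopes identical in both
sexes; batches act as additive offsets. Total tissue volume is the
row-sum of the generated region volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .io import CohortTable, RegionMeta

#: hard guard on any population correlation magnitude (Cholesky stability)
RHO_BOUND = 0.999


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_cohort`.

    Planted edges are ``(i, j, delta)`` with region indices into the
    generated region list and ``delta`` the female-minus-male population
    correlation difference. Planted volume effects map region index to a
    standardized male-minus-female mean shift (units of region SD).
    """

    n_female: int = 100
    n_male: int = 100
    p: int = 20
    base_correlation: float = 0.3
    block_sizes: Sequence[int] | None = None  # optional block structure
    within_block_rho: float | Sequence[float] = 0.5
    planted_edges: Sequence[tuple[int, int, float]] = field(default_factory=list)
    planted_volume_effects: dict[int, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (56.0, 90.0)      # days, mouse-like
    age_effect: tuple[float, float] = (0.0, 0.0)       # per-region slope range
    n_batches: int = 1
    batch_offsets: Sequence[float] | None = None       # additive, per batch
    base_mean: float = 100.0                           # mm³
    base_sd: float = 10.0                              # mm³ within-sex SD
    outlier_count: int = 0
    outlier_magnitude: float = 0.0                     # SD units
    seed: int = 0

    def region_ids(self) -> list[str]:
        """Alternating left/right homotopic pairs; midline remainder.

        Naming keeps generation order lexicographic so the canonical
        edge order equals the generation order.
        """
        ids = []
        for k in range(self.p // 2):
            ids.append(f"roi{k:03d}_left")
            ids.append(f"roi{k:03d}_right")
        if self.p % 2:
            ids.append(f"roi{self.p // 2:03d}_midline")
        return ids

    def population_correlations(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sex population correlation matrices (female, male)."""
        base = self._base_matrix()
        cf = base.copy()
        cm = base.copy()
        for i, j, delta in self.planted_edges:
            if i == j:
                raise ConfigurationError(f"planted self-edge ({i},{j})")
            rho = base[i, j]
            for val, sign in ((rho + delta / 2, "female"), (rho - delta / 2, "male")):
                if abs(val) > RHO_BOUND:
                    raise ConfigurationError(
                        f"planted edge ({i},{j},{delta}) pushes the {sign} "
                        f"correlation to {val:.4f}, beyond |rho| <= {RHO_BOUND}"
                    )
            cf[i, j] = cf[j, i] = rho + delta / 2
            cm[i, j] = cm[j, i] = rho - delta / 2
        for name, c in (("female", cf), ("male", cm)):
            lo = float(np.linalg.eigvalsh(c)[0])
            if lo < 1e-10:
                raise GenerationError(
                    f"implied {name} correlation matrix is not positive "
                    f"definite (smallest eigenvalue {lo:.3e})"
                )
        return cf, cm

    def _base_matrix(self) -> np.ndarray:
        if self.block_sizes is None:
            if abs(self.base_correlation) > RHO_BOUND:
                raise ConfigurationError("base_correlation out of bounds")
            c = np.full((self.p, self.p), self.base_correlation, dtype=float)
        else:
            if sum(self.block_sizes) != self.p:
                raise ConfigurationError("block_sizes must sum to p")
            c = np.full((self.p, self.p), self.base_correlation, dtype=float)
            rhos = self.within_block_rho
            if np.isscalar(rhos):
                rhos = [rhos] * len(self.block_sizes)
            if len(rhos) != len(self.block_sizes):
                raise ConfigurationError(
                    "within_block_rho must be scalar or one value per block"
                )
            start = 0
            for size, rho in zip(self.block_sizes, rhos):
                c[start:start + size, start:start + size] = rho
                start += size
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery testing."""

    true_sexdiff_edges: list[tuple[str, str, float]]
    true_volume_effects: dict[str, float]
    corr_female: np.ndarray
    corr_male: np.ndarray
    region_ids: list[str]


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, RegionMeta, GroundTruth]:
    """Draw a cohort with known covariance and volumetric sex structure.

    The same ``config`` (including seed) always yields byte-identical
    output.
    """
    cf, cm = config.population_correlations()
    rng = np.random.default_rng(config.seed)
    region_ids = config.region_ids()
    p = config.p

    lf = np.linalg.cholesky(cf)
    lm = np.linalg.cholesky(cm)
    zf = rng.standard_normal((config.n_female, p)) @ lf.T
    zm = rng.standard_normal((config.n_male, p)) @ lm.T

    # planted volumetric shifts, symmetric about the common mean
    shift = np.zeros(p)
    for idx, beta in config.planted_volume_effects.items():
        shift[idx] = beta
    vf = config.base_mean + config.base_sd * (zf - shift / 2.0)
    vm = config.base_mean + config.base_sd * (zm + shift / 2.0)
    volumes = np.vstack([vf, vm])
    n = config.n_female + config.n_male

    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    slopes = rng.uniform(config.age_effect[0], config.age_effect[1], size=p)
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    volumes = volumes + np.outer(age - mid_age, slopes)

    batches = np.array([f"batch{i % config.n_batches}" for i in range(n)])
    if config.batch_offsets is not None:
        if len(config.batch_offsets) != config.n_batches:
            raise ConfigurationError("batch_offsets length must equal n_batches")
        offs = np.asarray(config.batch_offsets, dtype=float)
        volumes = volumes + offs[np.arange(n) % config.n_batches][:, None]

    # enforce strict positivity with a per-region additive shift
    # (correlation-invariant)
    mins = volumes.min(axis=0)
    needs = mins <= 0
    if needs.any():
        volumes[:, needs] += (1.0 - mins[needs])

    subject_ids = [f"sub{i:04d}" for i in range(n)]
    sex = np.array(["female"] * config.n_female + ["male"] * config.n_male)
    subjects = pd.DataFrame(
        {"sex": sex, "age": age, "batch": batches},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    vol_df = pd.DataFrame(volumes, index=subjects.index, columns=region_ids)
    cohort = CohortTable(subjects=subjects, volumes=vol_df)

    if config.outlier_count:
        cohort, _ = inject_outliers(
            cohort, config.outlier_count, config.outlier_magnitude,
            seed=config.seed + 1,
        )

    meta = _region_meta(region_ids)
    truth = GroundTruth(
        true_sexdiff_edges=[
            (region_ids[i], region_ids[j], d) for i, j, d in config.planted_edges
        ],
        true_volume_effects={
            region_ids[i]: b for i, b in config.planted_volume_effects.items()
        },
        corr_female=cf,
        corr_male=cm,
        region_ids=region_ids,
    )
    return cohort, meta, truth


def _region_meta(region_ids: list[str]) -> RegionMeta:
    rows = []
    for rid in region_ids:
        if rid.endswith("_left"):
            hemi, partner = "left", rid[:-5] + "_right"
        elif rid.endswith("_right"):
            hemi, partner = "right", rid[:-6] + "_left"
        else:
            hemi, partner = "midline", None
        rows.append({"region_id": rid, "name": rid.replace("_", " "),
                     "hemisphere": hemi, "homotopic_partner": partner})
    table = pd.DataFrame(rows).set_index("region_id")
    return RegionMeta(table=table)


def inject_outliers(cohort: CohortTable, count: int, magnitude: float,
                    seed: int = 0) -> tuple[CohortTable, list[str]]:
    """Displace one random region volume for ``count`` random subjects by
    ``magnitude`` × that region's SD; returns the injected ids."""
    if count == 0:
        return cohort.copy(), []
    if magnitude <= 0:
        raise ConfigurationError("outlier magnitude must be > 0")
    if count >= cohort.n_subjects:
        raise ConfigurationError("outlier count must be < number of subjects")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    subj_idx = rng.choice(cohort.n_subjects, size=count, replace=False)
    ids = []
    for si in subj_idx:
        rj = int(rng.integers(0, len(cohort.region_ids)))
        col = cohort.region_ids[rj]
        sd = float(out.volumes[col].std(ddof=1))
        out.volumes.iloc[si, rj] += magnitude * sd
        ids.append(str(out.volumes.index[si]))
    out.subjects["ttv"] = out.volumes.sum(axis=1)
    return out, ids


def simulate_bounded_pairs(rho_grid: Sequence[float], delta: float,
                           n_per_group: int, n_reps: int,
                           seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo study of sex differences in a single correlation pair
    across a grid of baseline correlations.

    For each baseline ``rho0``, draws independent bivariate-normal pairs
    per sex with correlations ``rho0 + delta/2`` (female) and
    ``rho0 - delta/2`` (male) and summarizes the observed per-sex sample
    correlations. The asymptotic SD column uses
    ``sqrt(((1-rho_f^2)^2 + (1-rho_m^2)^2) / n)``, the large-n variance
    of the difference of two independent sample correlations.
    """
    for rho0 in rho_grid:
        for val in (rho0 + delta / 2, rho0 - delta / 2):
            if abs(val) > RHO_BOUND:
                raise ConfigurationError(
                    f"rho0={rho0} with delta={delta} implies correlation "
                    f"{val:.4f}, beyond |rho| <= {RHO_BOUND}"
                )
    if n_per_group < 4:
        raise ConfigurationError("n_per_group must be >= 4")
    rng = np.random.default_rng(seed)
    rows = []
    for rho0 in rho_grid:
        rho_f, rho_m = rho0 + delta / 2, rho0 - delta / 2
        diffs = np.empty(n_reps)
        strengths = np.empty(n_reps)
        for rep in range(n_reps):
            rf = _sample_corr(rng, rho_f, n_per_group)
            rm = _sample_corr(rng, rho_m, n_per_group)
            diffs[rep] = rf - rm
            strengths[rep] = 0.5 * (rf + rm)
        asym_sd = math.sqrt(
            ((1 - rho_f**2) ** 2 + (1 - rho_m**2) ** 2) / n_per_group
        )
        rows.append({
            "rho0": rho0,
            "mean_abs_diff": float(np.mean(np.abs(diffs))),
            "mean_diff": float(np.mean(diffs)),
            "sd_diff": float(np.std(diffs, ddof=1)),
            "mean_within_sex_r": float(np.mean(strengths)),
            "asymptotic_sd_diff": asym_sd,
        })
    return pd.DataFrame(rows)


def _sample_corr(rng: np.random.Generator, rho: float, n: int) -> float:
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rho * x + math.sqrt(1 - rho**2) * e
    return float(np.corrcoef(x, y)[0, 1])


def make_coupled_config(n_per_sex: int = 200, p: int = 30, rho0: float = 0.2,
                        n_biased_regions: int = 10, beta: float = 0.8,
                        delta: float = -0.3, seed: int = 0) -> SimConfig:
    """Config planting an inverse covariance–volume coupling.

    The first ``n_biased_regions`` regions get a male-biased volume shift
    (``+beta`` SD) and every edge among them a female-biased covariance
    difference (``delta < 0`` male-minus-female, i.e. the female
    correlation is larger), so the signed regional covariance bias
    correlates negatively with the volumetric sex effect.

    The block's base correlation is raised to ``rho0 + |delta|/2`` so the
    weaker sex's within-block correlation lands exactly back at ``rho0``
    — both implied per-sex matrices stay positive definite (a block whose
    within correlation dropped below the between-block background would
    not be).
    """
    edges = []
    for a in range(n_biased_regions):
        for b in range(a + 1, n_biased_regions):
            edges.append((a, b, -delta))  # stored female-minus-male
    effects = {r: beta for r in range(n_biased_regions)}
    return SimConfig(
        n_female=n_per_sex, n_male=n_per_sex, p=p, base_correlation=rho0,
        block_sizes=[n_biased_regions, p - n_biased_regions],
        within_block_rho=[rho0 + abs(delta) / 2, rho0],
        planted_edges=edges, planted_volume_effects=effects, seed=seed,
    )
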