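import numpy as np
import pandas as pd
import pytest

from sexcov import CohortTable, SimConfig, simulate_cohort
from sexcov.io import canonical_pairs
from sexcov.sexdiff import SexDiffResult


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted structure."""
    cfg = SimConfig(n_female=30, n_male=30, p=8, base_correlation=0.3, seed=42)
    cohort, meta, truth = simulate_cohort(cfg)
    return cohort, meta, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one strong planted covariance edge and one volume effect."""
    cfg = SimConfig(n_female=150, n_male=150, p=10, base_correlation=0.2,
                    planted_edges=[(0, 1, 0.6)],
                    planted_volume_effects={4: 0.8}, seed=7)
    cohort, meta, truth = simulate_cohort(cfg)
    return cohort, meta, truth


def make_cohort(vol: np.ndarray, sex: list[str], age=None, batch=None,
                qc=None) -> CohortTable:
    """Hand-built cohort from a raw volume matrix."""
    n, p = vol.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    subjects = pd.DataFrame({
        "sex": sex,
        "age": age if age is not None else np.linspace(50.0, 90.0, n),
        "batch": batch if batch is not None else ["b0"] * n,
    }, index=idx)
    if qc is not None:
        subjects["qc_covariate"] = qc
    volumes = pd.DataFrame(vol, index=idx,
                           columns=[f"r{j:02d}" for j in range(p)])
    return CohortTable(subjects=subjects, volumes=volumes)


def result_from_d(d: pd.DataFrame, significant=None) -> SexDiffResult:
    """SexDiffResult wrapper around a hand-built symmetric D matrix
    (r_female/r_male filled with consistent placeholders)."""
    regions = sorted(d.columns)
    d = d.loc[regions, regions]
    pairs = canonical_pairs(regions)
    dvals = np.array([d.loc[a, b] for a, b in pairs])
    sig = np.zeros(len(pairs), dtype=bool)
    if significant:
        sigset = {tuple(sorted(e)) for e in significant}
        sig = np.array([tuple(sorted(p_)) in sigset for p_ in pairs])
    rm = d / 2.0
    rf = -d / 2.0
    np.fill_diagonal(rm.values, 1.0)
    np.fill_diagonal(rf.values, 1.0)
    edges = pd.DataFrame({
        "region_i": [a for a, _ in pairs],
        "region_j": [b for _, b in pairs],
        "r_female": np.array([rf.loc[a, b] for a, b in pairs]),
        "r_male": np.array([rm.loc[a, b] for a, b in pairs]),
        "D": dvals,
        "p_perm": np.where(sig, 0.001, 0.5),
        "q": np.where(sig, 0.01, 0.8),
        "significant": sig,
    })
    return SexDiffResult(edges=edges, r_female=rf, r_male=rm,
                         sign_convention="male_minus_female",
                         n_perm=1000, seed=0, q_threshold=0.05)
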