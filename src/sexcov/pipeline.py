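"""End-to-end orchestration: QC → batch adjustment → edge-wise
permutation analysis → volumetric effects → regional summaries →
coupling, symmetry and network components → structured report.

Every stage's output is written as CSV with a provenance block (seed,
n_perm, package version, config hash) in a sidecar JSON, and a rerun
from the same config reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coupling import (coupling_permutation_test, female_biased_region_fraction,
                       hemispheric_symmetry, regional_mean_bias)
from .errors import ConfigurationError, ValidationError
from .io import (CohortTable, ColumnMap, RegionMeta, read_cohort,
                 read_region_meta, write_edge_table)
from .network import (build_graph, connected_components, graph_edge_list,
                      summarize_component)
from .qc import batch_adjust, flag_outliers_cooks, qc_threshold_filter, remove_flagged
from .sexdiff import SexDiffResult, compare_mean_correlations, run_sexdiff
from .synth import SimConfig, simulate_cohort
from .targeted import targeted_pairs_test
from .volumetrics import PROFILE_COVARIATES, volumetric_sex_effects, zscore_columns

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Single source of truth for a full pipeline run.

    Exactly one of (``cohort_path``, ``sim``) must be set: real tables in,
    or a synthetic cohort generated on the fly.
    """

    cohort_path: str | None = None
    region_meta_path: str | None = None
    sim: SimConfig | None = None
    species_profile: str = "mouse_like"     # selects covariate set
    qc_covariate: str | None = None         # e.g. Euler number column
    qc_threshold: float | None = None
    qc_direction: str = "min"
    remove_flagged_outliers: bool = False
    batch_method: str = "none"              # none | center | location_scale
    n_perm: int = 1000
    seed: int = 0
    q_threshold: float = 0.05
    sign_convention: str = "male_minus_female"
    permutation_mode: str = "full"
    top_k_components: int = 2
    targeted_regions: list[str] = field(default_factory=list)
    output_dir: str = "sexcov_output"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.sim is None):
            raise ConfigurationError(
                "exactly one of cohort_path or sim must be set"
            )
        if self.species_profile not in PROFILE_COVARIATES:
            raise ConfigurationError(
                f"unknown species profile {self.species_profile!r}"
            )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["planted_edges"] = [list(e) for e in self.sim.planted_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            s = dict(d["sim"])
            if "planted_edges" in s:
                s["planted_edges"] = [tuple(e) for e in s["planted_edges"]]
            if "planted_volume_effects" in s:
                s["planted_volume_effects"] = {
                    int(k): float(v) for k, v in s["planted_volume_effects"].items()
                }
            for key in ("age_range", "age_effect"):
                if s.get(key) is not None:
                    s[key] = tuple(s[key])
            d["sim"] = SimConfig(**s)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location does not affect results and is excluded)."""
        payload = self.to_dict()
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def summarize_fraction(n_significant: int, p: int) -> float:
    """Percent of all C(p,2) pairwise relationships that are significant."""
    if p < 2:
        raise ValidationError("need at least 2 regions")
    total = p * (p - 1) // 2
    if not 0 <= n_significant <= total:
        raise ValidationError(
            f"n_significant={n_significant} outside [0, C({p},2)={total}]"
        )
    return 100.0 * n_significant / total


def female_biased_edge_percent(sexdiff: SexDiffResult) -> float:
    """Percent of significant edges whose covariance difference is
    female-biased; NaN when there are no significant edges."""
    from .sexdiff import _sign_factor

    sig = sexdiff.significant_edges()
    if len(sig) == 0:
        return float("nan")
    sign = _sign_factor(sexdiff.sign_convention)
    d_mmf = sign * sig["D"].to_numpy()
    return 100.0 * float((d_mmf < 0).mean())


@dataclass
class ReportBundle:
    """All stage outputs plus the run summary and provenance."""

    cohort: CohortTable
    region_meta: RegionMeta | None
    sexdiff: SexDiffResult
    effects: "pd.DataFrame"
    regional: pd.DataFrame
    component_summaries: pd.DataFrame
    graph_edges: pd.DataFrame
    targeted: pd.DataFrame | None
    summary: dict
    provenance: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_table(self.sexdiff.edges, out / "edges.csv")
        self.effects.to_csv(out / "volumetric_effects.csv")
        self.regional.to_csv(out / "regional_bias.csv")
        self.component_summaries.to_csv(out / "components.csv", index=False)
        self.graph_edges.to_csv(out / "graph_edges.csv", index=False)
        if self.targeted is not None:
            self.targeted.to_csv(out / "targeted.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"summary": self.summary, "provenance": self.provenance},
                      fh, indent=2, sort_keys=True, default=_jsonable)
        with open(out / "summary.txt", "w") as fh:
            fh.write(render_summary(self.summary, self.provenance))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_summary(summary: dict, provenance: dict) -> str:
    lines = ["sexcov run summary", "=" * 19, ""]
    for key in sorted(summary):
        lines.append(f"{key}: {summary[key]}")
    lines.append("")
    lines.append("provenance:")
    for key in sorted(provenance):
        lines.append(f"  {key}: {provenance[key]}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _stage(name: str, t0: float, **counts) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring for stage order.

    Any stage error is re-raised with the stage name attached.
    """
    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.sim is not None:
            cohort, meta, _truth = simulate_cohort(config.sim)
        else:
            cohort, _dropped = read_cohort(config.cohort_path)
            meta = (read_region_meta(config.region_meta_path)
                    if config.region_meta_path else None)
        _stage(stage, t0, subjects=cohort.n_subjects,
               regions=len(cohort.region_ids))

        stage = "qc"
        t0 = time.perf_counter()
        excluded: list[str] = []
        if config.qc_covariate is not None and config.qc_threshold is not None:
            cohort, excluded = qc_threshold_filter(
                cohort, config.qc_covariate, config.qc_threshold,
                config.qc_direction,
            )
        outliers = flag_outliers_cooks(cohort)
        removed: list[str] = []
        if config.remove_flagged_outliers:
            cohort, removed = remove_flagged(cohort, outliers)
        _stage(stage, t0, excluded=len(excluded), flagged=len(outliers.flagged_ids),
               removed=len(removed))

        stage = "batch_adjust"
        t0 = time.perf_counter()
        cohort = batch_adjust(cohort, config.batch_method)
        _stage(stage, t0, method=config.batch_method)

        stage = "sexdiff"
        t0 = time.perf_counter()
        sexdiff = run_sexdiff(cohort, n_perm=config.n_perm, seed=config.seed,
                              sign_convention=config.sign_convention,
                              q_threshold=config.q_threshold,
                              mode=config.permutation_mode)
        _stage(stage, t0, n_edges=len(sexdiff.edges),
               n_significant=sexdiff.n_significant)

        stage = "volumetrics"
        t0 = time.perf_counter()
        covariates = PROFILE_COVARIATES[config.species_profile]
        usable = tuple(c for c in covariates
                       if c != "qc_covariate" or "qc_covariate" in cohort.subjects)
        effects = volumetric_sex_effects(zscore_columns(cohort), usable,
                                         config.q_threshold)
        _stage(stage, t0, regions=len(effects.table))

        stage = "regional_bias"
        t0 = time.perf_counter()
        regional = regional_mean_bias(sexdiff)
        _stage(stage, t0)

        stage = "coupling"
        t0 = time.perf_counter()
        coupling = {}
        for cmode in ("signed", "absolute"):
            res = coupling_permutation_test(
                cohort, mode=cmode, n_perm=config.n_perm,
                seed=config.seed + 1, covariates=usable,
                sign_convention=config.sign_convention,
            )
            coupling[cmode] = res
        _stage(stage, t0)

        stage = "symmetry"
        t0 = time.perf_counter()
        symmetry = None
        if meta is not None:
            try:
                symmetry = hemispheric_symmetry(regional, meta)
            except ValidationError:
                symmetry = None
        _stage(stage, t0)

        stage = "components"
        t0 = time.perf_counter()
        graph = build_graph(sexdiff, effects)
        comps = connected_components(graph, config.top_k_components) \
            if graph.number_of_nodes() else []
        comp_rows = [summarize_component(c).as_dict() for c in comps]
        component_summaries = pd.DataFrame(comp_rows)
        graph_edges = graph_edge_list(graph)
        _stage(stage, t0, components=len(comps))

        stage = "targeted"
        t0 = time.perf_counter()
        targeted = None
        if config.targeted_regions:
            targeted = targeted_pairs_test(
                cohort, list(config.targeted_regions), n_perm=config.n_perm,
                seed=config.seed, sign_convention=config.sign_convention,
                mode=config.permutation_mode,
            ).table
        _stage(stage, t0)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    # -- summary ------------------------------------------------------------
    p = len(cohort.region_ids)
    n_sig = sexdiff.n_significant
    mean_all = compare_mean_correlations(
        sexdiff.r_female, sexdiff.r_male,
        sign_convention=config.sign_convention, edge_subset="all")
    sig_mask = sexdiff.edges["significant"].to_numpy()
    mean_sig = None
    if sig_mask.sum() >= 2:
        mean_sig = compare_mean_correlations(
            sexdiff.r_female, sexdiff.r_male, edge_mask=sig_mask,
            sign_convention=config.sign_convention, edge_subset="significant")

    fbe = female_biased_edge_percent(sexdiff)
    summary = {
        "n_subjects": cohort.n_subjects,
        "n_regions": p,
        "n_edges": len(sexdiff.edges),
        "n_significant_edges": n_sig,
        "percent_significant": round(summarize_fraction(n_sig, p), 2),
        "percent_female_biased_edges":
            None if math.isnan(fbe) else round(fbe),
        "mean_corr_female_all": mean_all.mean_female,
        "mean_corr_male_all": mean_all.mean_male,
        "delta_all": mean_all.delta,
        "delta_all_ci": [mean_all.ci_low, mean_all.ci_high],
        "delta_significant": mean_sig.delta if mean_sig else None,
        "delta_significant_ci":
            [mean_sig.ci_low, mean_sig.ci_high] if mean_sig else None,
        "percent_regions_female_biased_all":
            100.0 * female_biased_region_fraction(
                regional, "mean_signed_all", config.sign_convention),
        "percent_regions_female_biased_sig": (
            lambda f: None if math.isnan(f) else 100.0 * f
        )(female_biased_region_fraction(
            regional, "mean_signed_sig", config.sign_convention)),
        "coupling_signed_r": coupling["signed"].r_obs,
        "coupling_signed_p": coupling["signed"].p_perm,
        "coupling_absolute_r": coupling["absolute"].r_obs,
        "coupling_absolute_p": coupling["absolute"].p_perm,
        "hemispheric_symmetry_r": symmetry[0] if symmetry else None,
        "hemispheric_symmetry_n_pairs": symmetry[1] if symmetry else None,
        "n_qc_excluded": len(excluded),
        "n_outliers_flagged": len(outliers.flagged_ids),
        "n_outliers_removed": len(removed),
    }
    provenance = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "sign_convention": config.sign_convention,
        "q_threshold": config.q_threshold,
        "permutation_mode": config.permutation_mode,
        "species_profile": config.species_profile,
        "config_hash": config.config_hash(),
        "sexcov_version": __version__,
    }
    return ReportBundle(
        cohort=cohort, region_meta=meta, sexdiff=sexdiff,
        effects=effects.table, regional=regional,
        component_summaries=component_summaries, graph_edges=graph_edges,
        targeted=targeted, summary=summary, provenance=provenance,
    )
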