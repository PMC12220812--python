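"""Data contracts and delimited-table I/O.

The pipeline's universal input is a :class:`CohortTable` — one row per
subject carrying sex, age, batch, an optional numeric QC covariate
(e.g. a surface-reconstruction Euler number), total tissue volume (TTV),
and a subjects × regions matrix of grey-matter volumes in mm³.
Region identity, hemisphere and homotopic pairing live in a
:class:`RegionMeta`. Edge-level results are exchanged as "edge tables":
one row per unordered region pair in a deterministic canonical order
(lexicographic by region id).

All files are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

SEX_LEVELS = ("female", "male")

#: minimum subjects per sex required at the I/O and QC boundaries,
#: mirroring the wild-type inclusion rule of at least 5 per sex
MIN_PER_SEX = 5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subject-by-region volume matrix plus per-subject covariates.

    Parameters
    ----------
    subjects
        DataFrame indexed by unique ``subject_id`` with columns
        ``sex`` (``"female"``/``"male"``), ``age`` (numeric), ``batch``
        (categorical label), optionally ``qc_covariate`` (numeric), and
        ``ttv`` (total grey-matter tissue volume, mm³).
    volumes
        DataFrame indexed identically, one numeric column per region,
        strictly positive volumes in mm³.
    """

    subjects: pd.DataFrame
    volumes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.subjects.index.equals(self.volumes.index):
            raise ValidationError("subjects and volumes indices differ")
        if self.subjects.index.has_duplicates:
            dups = self.subjects.index[self.subjects.index.duplicated()]
            raise ValidationError(f"duplicate subject_id: {sorted(set(dups))}")
        observed = set(self.subjects["sex"].unique())
        if not observed <= set(SEX_LEVELS):
            raise ValidationError(
                f"sex must be one of {SEX_LEVELS}, got {sorted(observed)}"
            )
        if len(observed) != 2:
            raise ValidationError("sex must have exactly two observed levels")
        if "ttv" not in self.subjects.columns:
            self.subjects = self.subjects.assign(
                ttv=self.volumes.sum(axis=1).astype(float)
            )

    # -- convenience ------------------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def sex(self) -> pd.Series:
        return self.subjects["sex"]

    def n_per_sex(self) -> dict[str, int]:
        counts = self.sex.value_counts()
        return {s: int(counts.get(s, 0)) for s in SEX_LEVELS}

    def check_min_per_sex(self, minimum: int = MIN_PER_SEX) -> None:
        counts = self.n_per_sex()
        bad = {s: n for s, n in counts.items() if n < minimum}
        if bad:
            raise ValidationError(
                f"inclusion rule requires at least {minimum} subjects per "
                f"sex; got {counts}"
            )

    def subset_subjects(self, keep: Sequence) -> "CohortTable":
        keep = list(keep)
        return CohortTable(
            subjects=self.subjects.loc[keep].copy(),
            volumes=self.volumes.loc[keep].copy(),
        )

    def subset_regions(self, regions: Sequence[str]) -> "CohortTable":
        missing = [r for r in regions if r not in self.volumes.columns]
        if missing:
            raise ValidationError(f"unknown region ids: {missing}")
        sub = self.subjects.copy()
        vols = self.volumes[list(regions)].copy()
        return CohortTable(subjects=sub, volumes=vols)

    def copy(self) -> "CohortTable":
        return CohortTable(self.subjects.copy(), self.volumes.copy())


@dataclass
class RegionMeta:
    """Region identifiers with hemisphere and homotopic-partner annotations.

    ``table`` is indexed by ``region_id`` with columns ``name``,
    ``hemisphere`` (``left``/``right``/``midline``) and
    ``homotopic_partner`` (region_id or missing).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "homotopic_partner"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"region metadata missing columns {sorted(missing)}")
        bad_hemi = set(self.table["hemisphere"].unique()) - {"left", "right", "midline"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        self._check_partner_symmetry()

    def _check_partner_symmetry(self) -> None:
        partners = self.table["homotopic_partner"]
        offending = []
        for rid, partner in partners.items():
            if pd.isna(partner) or partner == "":
                continue
            if partner == rid:
                offending.append((rid, partner))
                continue
            if partner not in self.table.index:
                offending.append((rid, partner))
                continue
            back = partners.loc[partner]
            if pd.isna(back) or back != rid:
                offending.append((rid, partner))
            if self.table.loc[rid, "hemisphere"] == "midline":
                offending.append((rid, partner))
        if offending:
            raise ValidationError(
                f"homotopic_partner mapping not symmetric for pairs: {offending}"
            )

    @property
    def region_ids(self) -> list[str]:
        return list(self.table.index)

    def homotopic_pairs(self) -> list[tuple[str, str]]:
        """Unordered (left, right) homotopic pairs, each reported once."""
        pairs = []
        for rid, row in self.table.iterrows():
            partner = row["homotopic_partner"]
            if pd.isna(partner) or partner == "":
                continue
            if row["hemisphere"] == "left":
                pairs.append((rid, partner))
        return pairs


# ---------------------------------------------------------------------------
# canonical edges
# ---------------------------------------------------------------------------

def canonical_pairs(region_ids: Iterable[str]) -> list[tuple[str, str]]:
    """All C(p,2) unordered region pairs in canonical (lexicographic) order."""
    return list(itertools.combinations(sorted(region_ids), 2))


def canonicalize_edges(table: pd.DataFrame) -> pd.DataFrame:
    """Return an edge table with (region_i, region_j) swapped into
    lexicographic order per row and rows sorted canonically."""
    if not {"region_i", "region_j"} <= set(table.columns):
        raise ValidationError("edge table requires region_i and region_j columns")
    t = table.copy()
    swap = t["region_i"] > t["region_j"]
    t.loc[swap, ["region_i", "region_j"]] = t.loc[
        swap, ["region_j", "region_i"]
    ].to_numpy()
    if (t["region_i"] == t["region_j"]).any():
        raise ValidationError("edge table contains self-pairs")
    t = t.sort_values(["region_i", "region_j"], kind="mergesort").reset_index(drop=True)
    if t.duplicated(["region_i", "region_j"]).any():
        raise ValidationError("edge table contains duplicate pairs")
    return t


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

@dataclass
class ColumnMap:
    """Column-mapping config for :func:`read_cohort`.

    ``regions`` may be an explicit list of region columns or ``None``,
    in which case every column not otherwise claimed is treated as a
    region volume.
    """

    subject: str = "subject_id"
    sex: str = "sex"
    age: str = "age"
    batch: str | None = "batch"
    qc_covariate: str | None = None
    ttv: str | None = "ttv"
    regions: Sequence[str] | None = None
    sex_values: Mapping[str, str] = field(
        default_factory=lambda: {"female": "female", "male": "male",
                                 "F": "female", "M": "male"}
    )


def read_cohort(path, colmap: ColumnMap | None = None,
                min_per_sex: int = MIN_PER_SEX) -> tuple[CohortTable, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Returns the cohort and a DataFrame reporting dropped rows
    (subject id + reason) for rows with missing sex or age.
    """
    colmap = colmap or ColumnMap()
    raw = pd.read_csv(path)
    for col, label in [(colmap.subject, "subject"), (colmap.sex, "sex"),
                       (colmap.age, "age")]:
        if col not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {col!r} (mapped as {label}) absent from {path}"
            )
    if raw[colmap.subject].duplicated().any():
        dups = raw.loc[raw[colmap.subject].duplicated(), colmap.subject]
        raise ValidationError(f"duplicate subject_id: {sorted(set(dups))}")

    dropped = raw[raw[colmap.sex].isna() | raw[colmap.age].isna()]
    report = pd.DataFrame({
        "subject_id": dropped[colmap.subject],
        "reason": "missing sex or age",
    })
    data = raw.drop(index=dropped.index).set_index(colmap.subject)
    data.index.name = "subject_id"

    sex = data[colmap.sex].map(lambda v: colmap.sex_values.get(v, v))
    claimed = {colmap.sex, colmap.age}
    subjects = pd.DataFrame({"sex": sex, "age": pd.to_numeric(data[colmap.age])})
    if colmap.batch is not None and colmap.batch in data.columns:
        subjects["batch"] = data[colmap.batch].astype(str)
        claimed.add(colmap.batch)
    else:
        subjects["batch"] = "batch0"
    if colmap.qc_covariate is not None:
        if colmap.qc_covariate not in data.columns:
            raise ConfigurationError(
                f"qc covariate column {colmap.qc_covariate!r} absent"
            )
        subjects["qc_covariate"] = pd.to_numeric(data[colmap.qc_covariate])
        claimed.add(colmap.qc_covariate)
    elif "qc_covariate" in data.columns:
        # a cohort written by this package round-trips its own column
        subjects["qc_covariate"] = pd.to_numeric(data["qc_covariate"])
        claimed.add("qc_covariate")
    if colmap.ttv is not None and colmap.ttv in data.columns:
        subjects["ttv"] = pd.to_numeric(data[colmap.ttv])
        claimed.add(colmap.ttv)

    if colmap.regions is not None:
        missing = [r for r in colmap.regions if r not in data.columns]
        if missing:
            raise ConfigurationError(f"region columns absent: {missing}")
        region_cols = list(colmap.regions)
    else:
        region_cols = [c for c in data.columns if c not in claimed]
    volumes = data[region_cols].apply(pd.to_numeric).astype(float)

    cohort = CohortTable(subjects=subjects, volumes=volumes)
    cohort.check_min_per_sex(min_per_sex)
    return cohort, report


def write_cohort(cohort: CohortTable, path) -> None:
    out = pd.concat([cohort.subjects, cohort.volumes], axis=1)
    out.index.name = "subject_id"
    out.to_csv(path)


def read_region_meta(path) -> RegionMeta:
    raw = pd.read_csv(path, dtype=str)
    if "region_id" not in raw.columns:
        raise ConfigurationError(f"region_id column absent from {path}")
    table = raw.set_index("region_id")
    return RegionMeta(table=table)


def write_region_meta(meta: RegionMeta, path) -> None:
    meta.table.to_csv(path)


def write_edge_table(table: pd.DataFrame, path) -> None:
    """Write an edge table CSV, one row per canonical unordered pair.

    Floats are written with shortest-roundtrip repr so that
    ``read_edge_table(write_edge_table(x)) == x`` at full precision.
    """
    if len(table):
        table = canonicalize_edges(table)
    table.to_csv(path, index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def expected_edge_count(p: int) -> int:
    return p * (p - 1) // 2
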