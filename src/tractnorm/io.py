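"""Cohort table ingestion and result-table output.

The single ingestion format is a delimited text table with one row per
subject carrying an identifier, a group label (control/patient), age in
years, one fractional-anisotropy (FA) value per named white-matter tract,
and optionally raw cognitive test scores.  A schema mapping assigns file
columns to these roles; tract names are free strings taken from the
column headers, never hard-coded.

Result tables are written as CSV with a commented metadata header block
(seed, permutation count, subset size, software version) so every output
file records the configuration that produced it.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__

CONTROL = "control"
PATIENT = "patient"
GROUPS = (CONTROL, PATIENT)

#: sentinel written for explicitly-missing numeric cells
MISSING_SENTINEL = "NA"


class SchemaError(ValueError):
    """A required column is absent or mis-declared."""


class CohortParseError(ValueError):
    """A cell could not be parsed; message names the row and column."""


class CohortValidationError(ValueError):
    """The parsed table violates a cohort invariant."""


@dataclass(frozen=True)
class CohortSchema:
    """Mapping from file columns to cohort roles.

    ``tracts=None`` means: every column not otherwise assigned is a tract.
    ``group_labels`` maps raw labels in the file onto the canonical
    ``control``/``patient`` pair.
    """

    id: str = "subject_id"
    group: str = "group"
    age: str = "age"
    tracts: tuple[str, ...] | None = None
    cognition: tuple[str, ...] = ()
    group_labels: Mapping[str, str] = field(
        default_factory=lambda: {CONTROL: CONTROL, PATIENT: PATIENT}
    )

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "CohortSchema":
        kw = dict(cfg)
        for key in ("tracts", "cognition"):
            if kw.get(key) is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSchema":
        """Load a schema from a YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_mapping(yaml.safe_load(text))
        return cls.from_mapping(json.loads(text))


@dataclass
class CohortTable:
    """Validated per-subject cohort: group, age, tract FA, cognition.

    ``data`` is indexed by subject id with columns ``group``, ``age``,
    the ordered tract columns and any cognitive-score columns.  Tract
    ordering is preserved from the source file and shared by every
    derived object downstream.
    """

    data: pd.DataFrame
    tracts: list[str]
    cognition: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate subject_id: {dups}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise CohortValidationError(
                f"group labels must be in {GROUPS}, found {sorted(bad)}"
            )
        if not self.tracts:
            raise CohortValidationError("cohort has no tract columns")
        for t in self.tracts:
            col = df[t]
            if col.isna().any():
                sid = df.index[col.isna()][0]
                raise CohortValidationError(
                    f"missing FA value for subject {sid!r}, tract {t!r}"
                )
        if (df["age"] <= 0).any():
            sid = df.index[df["age"] <= 0][0]
            raise CohortValidationError(f"non-positive age for subject {sid!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def ages(self) -> pd.Series:
        return self.data["age"]

    @property
    def fa(self) -> pd.DataFrame:
        """Subjects x tracts FA matrix, tract order preserved."""
        return self.data[self.tracts]

    @property
    def controls(self) -> "CohortTable":
        return self.subset(self.data["group"] == CONTROL)

    @property
    def patients(self) -> "CohortTable":
        return self.subset(self.data["group"] == PATIENT)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.data.loc[mask], list(self.tracts), list(self.cognition))

    @property
    def n_controls(self) -> int:
        return int((self.data["group"] == CONTROL).sum())

    @property
    def n_patients(self) -> int:
        return int((self.data["group"] == PATIENT).sum())


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(
    path: str | Path,
    schema: CohortSchema | Mapping | None = None,
    sep: str | None = None,
) -> CohortTable:
    """Read and validate a cohort table from CSV/TSV.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Column-role mapping; defaults to the canonical column names with
        every unassigned column treated as a tract.
    sep
        Field delimiter; inferred from the extension when omitted.

    Raises
    ------
    SchemaError
        if a mapped column is absent.
    CohortParseError
        if a tract cell is non-numeric, naming the subject and column.
    CohortValidationError
        for duplicate ids, bad group labels or missing FA.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = CohortSchema()
    elif not isinstance(schema, CohortSchema):
        schema = CohortSchema.from_mapping(schema)

    raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, comment="#")
    return cohort_from_raw(raw, schema, source=path.name)


def cohort_from_raw(
    raw: pd.DataFrame, schema: CohortSchema | Mapping | None = None,
    source: str = "<dataframe>",
) -> CohortTable:
    """Validate an in-memory raw table (string-typed ok) into a CohortTable."""
    if schema is None:
        schema = CohortSchema()
    elif not isinstance(schema, CohortSchema):
        schema = CohortSchema.from_mapping(schema)
    raw = raw.astype(str) if not all(raw.dtypes == object) else raw
    for col in (schema.id, schema.group, schema.age):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} not found in {source}")
    reserved = {schema.id, schema.group, schema.age, *schema.cognition}
    if schema.tracts is None:
        tracts = [c for c in raw.columns if c not in reserved]
    else:
        missing = [c for c in schema.tracts if c not in raw.columns]
        if missing:
            raise SchemaError(f"declared tract columns absent: {missing}")
        tracts = list(schema.tracts)
    if not tracts:
        raise SchemaError("no tract columns identified")
    missing_cog = [c for c in schema.cognition if c not in raw.columns]
    if missing_cog:
        raise SchemaError(f"declared cognition columns absent: {missing_cog}")

    df = pd.DataFrame(index=pd.Index(raw[schema.id].astype(str), name="subject_id"))
    labels = raw[schema.group].astype(str).str.strip().str.lower()
    df["group"] = [schema.group_labels.get(v, v) for v in labels]
    df["age"] = _numeric(raw, schema.age, source)
    for t in tracts:
        df[t] = _numeric(raw, t, source, allow_missing=False)
    for c in schema.cognition:
        df[c] = _numeric(raw, c, source, allow_missing=True)
    return CohortTable(df, tracts, list(schema.cognition))


def _numeric(raw: pd.DataFrame, col: str, source: str, allow_missing: bool = False):
    vals = pd.to_numeric(raw[col].replace({MISSING_SENTINEL: np.nan, "": np.nan}),
                         errors="coerce")
    newly_bad = vals.isna() & raw[col].notna() & ~raw[col].isin([MISSING_SENTINEL, ""])
    if newly_bad.any():
        row = int(np.flatnonzero(newly_bad)[0])
        raise CohortParseError(
            f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, "
            f"data row {row + 1} of {source}"
        )
    if not allow_missing and vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise CohortParseError(
            f"missing value in column {col!r}, data row {row + 1} of {source}"
        )
    return vals.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# result tables


@dataclass
class ResultTable:
    """A result table plus the metadata block written above it."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        num = self.data.select_dtypes(include=[float, int])
        if np.isinf(num.to_numpy(dtype=float)).any():
            raise CohortValidationError("result table contains non-finite values")


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a ResultTable as CSV with a commented metadata header.

    The round trip through :func:`read_results` reproduces every finite
    value to full precision; missing cells are written as ``NA``.
    """
    path = Path(path)
    meta = {"software": f"tractnorm {__version__}", **table.metadata}
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    table.data.to_csv(buf, na_rep=MISSING_SENTINEL, float_format="%.17g")
    path.write_text(buf.getvalue())


def read_results(path: str | Path) -> ResultTable:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", index_col=0, na_values=[MISSING_SENTINEL])
    return ResultTable(df, meta)
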