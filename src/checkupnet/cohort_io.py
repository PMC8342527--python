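"""Cohort table input/output and longitudinal pairing.

A cohort table is a subjects-by-variables grid at one timepoint.  Variables
are described by :class:`VariableDescriptor` (continuous measurement, binary,
ordinal or nominal questionnaire answer); values of the categorical kinds are
stored as their declared text levels, continuous values as floats, and missing
cells as NaN.  The file dialect is fixed: comma-separated UTF-8 with a header
row, subject identifiers in a ``subject_id`` column, continuous values written
with six decimals.  Edge lists (ranked variable-pair association records) are
tab-separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ID_COLUMN = "subject_id"
DEFAULT_MISSING_TOKEN = "NA"
_CONTINUOUS_FORMAT = "{:.6f}"

VALID_KINDS = ("continuous", "binary", "ordinal", "categorical")


@dataclass(frozen=True)
class VariableDescriptor:
    """Schema entry for one cohort variable.

    ``ordinal_levels`` lists the declared answer labels in order (required for
    the binary/ordinal/categorical kinds); ``numeric_map`` optionally maps
    labels to analysis-scale numbers (e.g. a dose band to its mean grams).
    """

    name: str
    kind: str
    units: str = ""
    ordinal_levels: tuple[str, ...] = ()
    numeric_map: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "ordinal_levels", tuple(self.ordinal_levels))
        if self.kind != "continuous" and len(self.ordinal_levels) < 2:
            raise ValueError(
                f"{self.kind} variable {self.name!r} needs at least 2 declared levels"
            )
        if self.kind == "binary" and len(self.ordinal_levels) != 2:
            raise ValueError(f"binary variable {self.name!r} needs exactly 2 levels")
        if self.numeric_map is not None:
            unknown = set(self.numeric_map) - set(self.ordinal_levels)
            if unknown:
                raise ValueError(
                    f"numeric_map of {self.name!r} names undeclared levels {sorted(unknown)}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.kind != "continuous"


@dataclass
class CohortTable:
    """Subjects x variables at one timepoint, with NaN as the missing marker."""

    data: pd.DataFrame
    variables: tuple[VariableDescriptor, ...]
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        if list(self.data.columns) != names:
            raise ValueError("table columns do not match schema variable order")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if len(self.data) < 2:
            raise ValueError("a cohort table needs at least 2 subjects")
        for desc in self.variables:
            col = self.data[desc.name]
            if desc.is_categorical:
                bad = col.dropna()[~col.dropna().isin(desc.ordinal_levels)]
                if len(bad):
                    raise ValueError(
                        f"undeclared level {bad.iloc[0]!r} of {desc.name!r} "
                        f"(subject {bad.index[0]!r})"
                    )
            else:
                self.data[desc.name] = pd.to_numeric(col, errors="raise")

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def descriptor(self, name: str) -> VariableDescriptor:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        return CohortTable(
            self.data.loc[list(subject_ids)].copy(), self.variables, self.timepoint
        )


@dataclass
class PairedCohort:
    """Baseline and follow-up tables of the same cohort with the paired IDs."""

    baseline: CohortTable
    followup: CohortTable
    paired_ids: tuple[str, ...]
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.paired_ids = tuple(self.paired_ids)
        base = set(self.baseline.subject_ids)
        fol = set(self.followup.subject_ids)
        if not set(self.paired_ids) <= (base & fol):
            raise ValueError("paired_ids must be present in both tables")
        if self.baseline.timepoint == self.followup.timepoint:
            raise ValueError("baseline and followup must have distinct timepoints")

    @property
    def n(self) -> int:
        return len(self.paired_ids)

    def wide(self) -> pd.DataFrame:
        """Paired subjects with columns ``<var>__baseline`` / ``<var>__followup``."""
        ids = list(self.paired_ids)
        b = self.baseline.data.loc[ids].add_suffix("__baseline")
        f = self.followup.data.loc[ids].add_suffix("__followup")
        return pd.concat([b, f], axis=1)


def read_cohort_table(
    path: str | Path,
    schema: Sequence[VariableDescriptor],
    missing_token: str = DEFAULT_MISSING_TOKEN,
    timepoint: str = "",
) -> CohortTable:
    """Parse a CSV cohort file against a schema.

    Cells equal to ``missing_token`` (or empty) become missing; unparseable
    continuous cells become missing; undeclared categorical levels and
    duplicate subject IDs are hard errors.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if ID_COLUMN not in raw.columns:
        raise ValueError(f"file {path} lacks the {ID_COLUMN!r} column")
    dup = raw[ID_COLUMN][raw[ID_COLUMN].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id {dup.iloc[0]!r} in {path}")
    missing = {missing_token, ""}
    columns: dict[str, pd.Series] = {}
    for desc in schema:
        if desc.name not in raw.columns:
            raise ValueError(f"schema column {desc.name!r} absent from {path}")
        col = raw[desc.name].where(~raw[desc.name].isin(missing), other=np.nan)
        if desc.is_categorical:
            present = col.dropna()
            bad = present[~present.isin(desc.ordinal_levels)]
            if len(bad):
                row = raw[ID_COLUMN].iloc[bad.index[0]]
                raise ValueError(
                    f"undeclared level {bad.iloc[0]!r} in column {desc.name!r} "
                    f"(subject {row!r})"
                )
            columns[desc.name] = col
        else:
            columns[desc.name] = pd.to_numeric(col, errors="coerce")
    data = pd.DataFrame(columns)
    data.index = pd.Index(raw[ID_COLUMN], name=ID_COLUMN)
    return CohortTable(data, tuple(schema), timepoint)


def write_cohort_table(
    table: CohortTable,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write a cohort CSV; continuous values use a fixed 6-decimal format."""
    out = pd.DataFrame(index=table.data.index)
    for desc in table.variables:
        col = table.data[desc.name]
        if desc.is_categorical:
            out[desc.name] = col.fillna(missing_token)
        else:
            out[desc.name] = [
                missing_token if pd.isna(v) else _CONTINUOUS_FORMAT.format(v)
                for v in col
            ]
    out.reset_index().to_csv(path, index=False, lineterminator="\n")


def align_longitudinal_pairs(
    baseline: CohortTable,
    followup: CohortTable,
    required_vars: Sequence[str] = (),
) -> PairedCohort:
    """Pair subjects present at both timepoints with complete required variables.

    Exclusion counts are recorded by reason (present at one timepoint only, or
    missing a required variable at either timepoint), mirroring a study flow
    chart.
    """
    for name in required_vars:
        if name not in baseline.variable_names or name not in followup.variable_names:
            raise ValueError(f"required variable {name!r} absent from a timepoint")
    base_ids = set(baseline.subject_ids)
    fol_ids = set(followup.subject_ids)
    both = [sid for sid in baseline.subject_ids if sid in fol_ids]
    if not both:
        raise ValueError("no subjects shared between the two timepoints")
    exclusions = {
        "baseline_only": len(base_ids - fol_ids),
        "followup_only": len(fol_ids - base_ids),
        "missing_required": 0,
    }
    if required_vars:
        req = list(required_vars)
        ok_base = baseline.data.loc[both, req].notna().all(axis=1)
        ok_fol = followup.data.loc[both, req].notna().all(axis=1)
        keep = ok_base.to_numpy() & ok_fol.to_numpy()
        exclusions["missing_required"] = int((~keep).sum())
        paired = [sid for sid, k in zip(both, keep) if k]
    else:
        paired = both
    return PairedCohort(baseline, followup, tuple(paired), exclusions)


# ---------------------------------------------------------------------------
# edge lists

EDGE_COLUMNS = ("var1", "var2", "r", "rank", "significant")


def write_edge_list(edges: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a ranked association edge list as TSV.

    Rows are ordered by rank then lexicographic (var1, var2) pair, so output
    is deterministic regardless of input order.
    """
    df = pd.DataFrame(edges, columns=list(EDGE_COLUMNS))
    df = df.sort_values(["rank", "var1", "var2"], kind="mergesort").reset_index(drop=True)
    df["r"] = [_CONTINUOUS_FORMAT.format(v) for v in df["r"].astype(float)]
    df["significant"] = df["significant"].astype(bool).map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"var1": str, "var2": str})
    df["r"] = df["r"].astype(float)
    df["rank"] = df["rank"].astype(int)
    df["significant"] = df["significant"].map({"true": True, "false": False, True: True, False: False})
    return df


# ---------------------------------------------------------------------------
# YAML schemas

def load_schema(path: str | Path) -> tuple[VariableDescriptor, ...]:
    """Load a YAML mapping name -> {kind, units, levels, numeric_map}."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"schema file {path} must be a mapping of variable names")
    out = []
    for name, spec in doc.items():
        spec = spec or {}
        out.append(
            VariableDescriptor(
                name=str(name),
                kind=spec.get("kind", "continuous"),
                units=spec.get("units", "") or "",
                ordinal_levels=tuple(spec.get("levels", ()) or ()),
                numeric_map={str(k): float(v) for k, v in spec["numeric_map"].items()}
                if spec.get("numeric_map")
                else None,
            )
        )
    return tuple(out)


def save_schema(schema: Sequence[VariableDescriptor], path: str | Path) -> None:
    doc: dict[str, dict] = {}
    for desc in schema:
        entry: dict = {"kind": desc.kind}
        if desc.units:
            entry["units"] = desc.units
        if desc.ordinal_levels:
            entry["levels"] = list(desc.ordinal_levels)
        if desc.numeric_map is not None:
            entry["numeric_map"] = {k: float(v) for k, v in desc.numeric_map.items()}
        doc[desc.name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
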