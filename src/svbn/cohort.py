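"""Cohort tables: reading, validation, complete-case filtering, dichotomization.

A cohort is a subject-by-variable table mixing continuous outcomes (Bayley
MDI/PDI points, length-for-age z-scores, birthweight in grams, ventilation
days, gestational weeks, census SES score units) and binary flags (sex,
damaging-genotype indicators).  Continuous variables enter the network
analysis only after dichotomization by an explicit :class:`ThresholdRule`;
missing data are handled strictly by complete-case filtering, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "ThresholdRule",
    "DiscreteCohort",
    "CohortError",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "read_cohort",
    "filter_complete_cases",
    "apply_thresholds",
    "write_discrete_cohort",
    "read_discrete_cohort",
    "STANDARD_RULES",
]

DEFAULT_MISSING_TOKENS = ("", "na", "nan")

TRUE_TOKENS = {"true", "t", "1", "yes"}
FALSE_TOKENS = {"false", "f", "0", "no"}


class CohortError(Exception):
    """Base class for cohort-handling errors."""


class SchemaError(CohortError):
    """A declared column is absent or of the wrong kind."""


class ValidationError(CohortError):
    """A table-level invariant is violated (e.g. duplicate subject id)."""


class ParseError(CohortError):
    """A cell could not be interpreted under its column's declared kind."""


@dataclass(frozen=True)
class ThresholdRule:
    """Dichotomization rule: flag a continuous value by comparison to a cutoff.

    ``direction`` is one of ``"le"`` (value <= cutoff is flagged), ``"lt"``
    (value < cutoff) or ``"gt"`` (value > cutoff); the comparators are taken
    literally, so MDI <= 70 is "low" while MDI = 100 under a "> 100" favorable
    rule is *not* flagged.
    """

    variable: str
    cutoff: float
    direction: str
    flag_label: str
    complement_label: str

    def __post_init__(self) -> None:
        if self.direction not in ("le", "lt", "gt"):
            raise ValidationError(
                f"direction must be one of le/lt/gt, got {self.direction!r}"
            )
        if not np.isfinite(self.cutoff):
            raise ValidationError(f"cutoff must be finite, got {self.cutoff!r}")
        if self.flag_label == self.complement_label:
            raise ValidationError("flag and complement labels must differ")

    def applies(self, values: np.ndarray) -> np.ndarray:
        """Boolean flag array for a float vector (NaN propagates as False)."""
        if self.direction == "le":
            return values <= self.cutoff
        if self.direction == "lt":
            return values < self.cutoff
        return values > self.cutoff

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "cutoff": self.cutoff,
            "direction": self.direction,
            "flag_label": self.flag_label,
            "complement_label": self.complement_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdRule":
        return cls(
            variable=d["variable"],
            cutoff=float(d["cutoff"]),
            direction=d["direction"],
            flag_label=d["flag_label"],
            complement_label=d["complement_label"],
        )


#: The fixed dichotomization rules used throughout the analysis: adverse
#: outcome cutoffs (MDI/PDI <= 70 low, LAZ <= -1.6 low), favorable outcome
#: cutoffs (MDI/PDI > 100, LAZ > 0), and the previously published clinical
#: cutoffs (birthweight < 2500 g low, ventilation > 7 d prolonged,
#: gestational age < 37 wk preterm, census SES score < -0.3 low).
STANDARD_RULES: dict[str, ThresholdRule] = {
    "MDI_low": ThresholdRule("MDI", 70.0, "le", "low", "not_low"),
    "PDI_low": ThresholdRule("PDI", 70.0, "le", "low", "not_low"),
    "LAZ_low": ThresholdRule("LAZ", -1.6, "le", "low", "not_low"),
    "MDI_favorable": ThresholdRule("MDI", 100.0, "gt", "normal", "not_normal"),
    "PDI_favorable": ThresholdRule("PDI", 100.0, "gt", "normal", "not_normal"),
    "LAZ_favorable": ThresholdRule("LAZ", 0.0, "gt", "normal", "not_normal"),
    "BWT_low": ThresholdRule("BWT", 2500.0, "lt", "low", "not_low"),
    "VENT_prolonged": ThresholdRule("VENT", 7.0, "gt", "prolonged", "not_prolonged"),
    "PRETERM": ThresholdRule("GA", 37.0, "lt", "preterm", "term"),
    "SES_low": ThresholdRule("SES", -0.3, "lt", "low", "not_low"),
}


@dataclass
class CohortTable:
    """Raw cohort: one row per subject, columns continuous or binary.

    ``data`` holds floats for continuous columns (NaN = missing) and pandas
    nullable booleans for binary columns (pd.NA = missing); ``kinds`` maps
    each analysis column to ``"continuous"`` or ``"binary"``.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = [str(i) for i in self.data.index]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            seen: set[str] = set()
            for sid in self.subject_ids:
                if sid in seen:
                    raise ValidationError(f"duplicate subject_id {sid!r}")
                seen.add(sid)
        for name, kind in self.kinds.items():
            if name not in self.data.columns:
                raise SchemaError(f"declared column {name!r} missing from table")
            if kind not in ("continuous", "binary"):
                raise SchemaError(f"unknown kind {kind!r} for column {name!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.kinds:
            raise SchemaError(f"unknown variable {name!r}")
        return self.data[name]


@dataclass
class DiscreteCohort:
    """Fully categorical complete-case cohort ready for network learning.

    Every cell is a member of its column's declared state set; downstream
    stages (scoring, search, inference) require completeness, which is
    enforced at construction.
    """

    data: pd.DataFrame
    state_sets: dict[str, tuple[str, ...]]
    subject_ids: list[str] = field(default_factory=list)
    provenance: tuple[ThresholdRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = [str(i) for i in self.data.index]
        for name, states in self.state_sets.items():
            if name not in self.data.columns:
                raise SchemaError(f"declared column {name!r} missing from table")
            col = self.data[name]
            if col.isna().any():
                raise ValidationError(f"missing cells in column {name!r}")
            bad = set(col.unique()) - set(states)
            if bad:
                raise ValidationError(
                    f"column {name!r} contains undeclared states {sorted(bad)}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return list(self.state_sets)

    def codes(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Integer-coded matrix (rows x variables), codes indexing state sets."""
        names = list(order) if order is not None else self.variables
        out = np.empty((len(self.data), len(names)), dtype=np.int64)
        for j, name in enumerate(names):
            states = self.state_sets[name]
            lut = {s: i for i, s in enumerate(states)}
            out[:, j] = self.data[name].map(lut).to_numpy()
        return out


def _parse_binary_cell(token: str, row: int, column: str) -> object:
    low = token.strip().lower()
    if low in TRUE_TOKENS:
        return True
    if low in FALSE_TOKENS:
        return False
    raise ParseError(
        f"row {row}, column {column!r}: cannot parse {token!r} as binary"
    )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str],
    *,
    delimiter: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    subject_id_column: str = "subject_id",
) -> CohortTable:
    """Read a delimited cohort file under a column-kind schema.

    Delimiter is inferred from the extension (``.tsv`` -> tab, else comma)
    unless given explicitly.  Cells matching ``missing_tokens``
    (case-insensitively) become missing; any other unparseable cell raises
    :class:`ParseError` naming the row and column.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = {t.lower() for t in missing_tokens}

    unknown = set(schema) - set(raw.columns)
    if unknown:
        raise SchemaError(f"schema names absent from header: {sorted(unknown)}")

    if subject_id_column in raw.columns:
        subject_ids = [s.strip() for s in raw[subject_id_column]]
    else:
        subject_ids = [str(i) for i in range(len(raw))]
    seen: set[str] = set()
    for sid in subject_ids:
        if sid in seen:
            raise ValidationError(f"duplicate subject_id {sid!r}")
        seen.add(sid)

    cols: dict[str, object] = {}
    for name, kind in schema.items():
        tokens = raw[name]
        if kind == "continuous":
            values = np.full(len(tokens), np.nan)
            for i, tok in enumerate(tokens):
                if tok.strip().lower() in missing:
                    continue
                try:
                    values[i] = float(tok)
                except ValueError:
                    raise ParseError(
                        f"row {i}, column {name!r}: non-numeric token {tok!r}"
                    ) from None
            cols[name] = values
        elif kind == "binary":
            vals: list[object] = []
            for i, tok in enumerate(tokens):
                if tok.strip().lower() in missing:
                    vals.append(pd.NA)
                else:
                    vals.append(_parse_binary_cell(tok, i, name))
            cols[name] = pd.array(vals, dtype="boolean")
        else:
            raise SchemaError(f"unknown kind {kind!r} for column {name!r}")

    frame = pd.DataFrame(cols)
    return CohortTable(data=frame, kinds=dict(schema), subject_ids=subject_ids)


def filter_complete_cases(
    table: CohortTable, variables: Sequence[str]
) -> tuple[CohortTable, int]:
    """Keep rows with no missing cell among ``variables``; order preserved.

    Returns the filtered table and the count of rows removed.  An empty
    variable list is a vacuous condition and returns the table unchanged.
    """
    for v in variables:
        if v not in table.kinds:
            raise SchemaError(f"unknown variable {v!r}")
    if not variables:
        return table, 0
    keep = np.ones(table.n_subjects, dtype=bool)
    for v in variables:
        keep &= ~table.data[v].isna().to_numpy()
    removed = int((~keep).sum())
    new = CohortTable(
        data=table.data.loc[keep].reset_index(drop=True),
        kinds=dict(table.kinds),
        subject_ids=[s for s, k in zip(table.subject_ids, keep) if k],
    )
    return new, removed


def apply_thresholds(
    table: CohortTable,
    rules: Sequence[ThresholdRule],
    *,
    binary_labels: tuple[str, str] = ("true", "false"),
    rename: Mapping[str, str] | None = None,
) -> DiscreteCohort:
    """Dichotomize continuous columns per the rules; binary columns pass through.

    Each rule's column must be continuous (a rule on an already-binary column
    is rejected rather than silently re-applied).  Output columns may be
    renamed via ``rename`` (e.g. ``{"MDI": "MDI_low"}``).  Rows with any
    missing cell among the output columns are rejected: run
    :func:`filter_complete_cases` first.
    """
    rename = dict(rename or {})
    by_var: dict[str, ThresholdRule] = {}
    for rule in rules:
        if rule.variable not in table.kinds:
            raise SchemaError(f"rule on absent column {rule.variable!r}")
        if table.kinds[rule.variable] != "continuous":
            raise ValidationError(
                f"rule on non-continuous column {rule.variable!r}"
            )
        if rule.variable in by_var:
            raise ValidationError(f"duplicate rule for column {rule.variable!r}")
        by_var[rule.variable] = rule

    cols: dict[str, pd.Series] = {}
    state_sets: dict[str, tuple[str, ...]] = {}
    for name, kind in table.kinds.items():
        out_name = rename.get(name, name)
        if kind == "binary":
            col = table.data[name]
            if col.isna().any():
                raise ValidationError(
                    f"missing cells in column {name!r}; filter complete cases first"
                )
            t, f = binary_labels
            cols[out_name] = col.map({True: t, False: f}).astype(str)
            state_sets[out_name] = (t, f)
        elif name in by_var:
            rule = by_var[name]
            values = table.data[name].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValidationError(
                    f"missing cells in column {name!r}; filter complete cases first"
                )
            flags = rule.applies(values)
            labels = np.where(flags, rule.flag_label, rule.complement_label)
            cols[out_name] = pd.Series(labels)
            state_sets[out_name] = (rule.flag_label, rule.complement_label)
        # continuous columns without a rule are dropped from the discrete view

    frame = pd.DataFrame(cols)
    return DiscreteCohort(
        data=frame,
        state_sets=state_sets,
        subject_ids=list(table.subject_ids),
        provenance=tuple(rules),
    )


def write_discrete_cohort(cohort: DiscreteCohort, path: str | Path) -> None:
    """Write a DiscreteCohort as TSV plus a JSON sidecar with the state sets
    and threshold provenance (bit-exact round trip)."""
    path = Path(path)
    out = cohort.data.copy()
    out.insert(0, "subject_id", cohort.subject_ids)
    out.to_csv(path, sep="\t", index=False)
    sidecar = {
        "state_sets": {k: list(v) for k, v in cohort.state_sets.items()},
        "rules": [r.to_dict() for r in cohort.provenance],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_discrete_cohort(path: str | Path) -> DiscreteCohort:
    """Inverse of :func:`write_discrete_cohort`."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    subject_ids = list(frame.pop("subject_id"))
    return DiscreteCohort(
        data=frame,
        state_sets={k: tuple(v) for k, v in sidecar["state_sets"].items()},
        subject_ids=subject_ids,
        provenance=tuple(ThresholdRule.from_dict(d) for d in sidecar["rules"]),
    )
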