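"""Cohort data model and delimited-table IO.

A cohort is a flat patient table: binary/categorical aberration and clinical
indicators (the discrete proxies x1), real-valued expression and clinical
measurements (the continuous proxies x2), one designated binary intervention
column t (a genomic aberration), an integer Gleason Score outcome y, and a
race/ethnicity label.  Synthetic cohorts additionally carry a truth block
with both potential outcomes.

The :class:`FeatureSchema` declares each column's role; :class:`CohortTable`
couples a validated :class:`pandas.DataFrame` with its schema.  Files are
plain delimited text (tab emitted; tab or comma accepted on read).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RACE_LEVELS = ("EA", "AA", "Asian", "unknown")

#: Synonyms folded into the closed race vocabulary at read time
#: (case-insensitive).  Unrecognized or empty labels become "unknown".
_RACE_SYNONYMS = {
    "ea": "EA",
    "white": "EA",
    "caucasian": "EA",
    "european american": "EA",
    "european-american": "EA",
    "aa": "AA",
    "black": "AA",
    "black or african american": "AA",
    "african american": "AA",
    "african-american": "AA",
    "asian": "Asian",
}

TRUTH_COLUMNS = ("y0_true", "y1_true")
LATENT_TRUTH_COLUMNS = ("y0_latent", "y1_latent")

GS_MIN, GS_MAX = 2, 10


class SchemaError(ValueError):
    """A column required by the schema is absent or mis-declared."""


class CohortValidationError(ValueError):
    """Table contents violate the cohort contract (bad t, y, ...)."""


@dataclass(frozen=True)
class FeatureSchema:
    """Column roles for a cohort table.

    Parameters
    ----------
    discrete_columns
        Binary or small-cardinality categorical proxy columns (x1).
    continuous_columns
        Real-valued proxy columns (x2): gene expression, continuous clinical.
    treatment_column
        The binary intervention (1 = aberration present).
    outcome_column
        Integer Gleason Score.
    race_column
        Race/ethnicity label, normalized to ``RACE_LEVELS``.
    aberration_expression_map
        Maps each aberration name to the continuous columns carrying that
        gene's expression (possibly empty, e.g. germline variants).  Used by
        :func:`exclude_intervention_expression`.
    """

    discrete_columns: tuple[str, ...]
    continuous_columns: tuple[str, ...]
    treatment_column: str
    outcome_column: str
    race_column: str
    aberration_expression_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "discrete_columns", tuple(self.discrete_columns))
        object.__setattr__(self, "continuous_columns", tuple(self.continuous_columns))
        object.__setattr__(
            self,
            "aberration_expression_map",
            {k: tuple(v) for k, v in self.aberration_expression_map.items()},
        )
        self.validate()

    def validate(self) -> None:
        disc, cont = set(self.discrete_columns), set(self.continuous_columns)
        if disc & cont:
            raise SchemaError(f"columns in both proxy lists: {sorted(disc & cont)}")
        special = {self.treatment_column, self.outcome_column, self.race_column}
        if len(special) != 3:
            raise SchemaError("treatment/outcome/race columns must be distinct")
        clash = special & (disc | cont)
        if clash:
            raise SchemaError(
                f"treatment/outcome/race columns may not be proxies: {sorted(clash)}"
            )
        for ab, cols in self.aberration_expression_map.items():
            missing = set(cols) - cont
            if missing:
                raise SchemaError(
                    f"aberration {ab!r} maps to non-continuous columns {sorted(missing)}"
                )

    @property
    def all_columns(self) -> tuple[str, ...]:
        return (
            *self.discrete_columns,
            *self.continuous_columns,
            self.treatment_column,
            self.outcome_column,
            self.race_column,
        )

    def fingerprint(self) -> str:
        """Stable hash of the schema, embedded in model checkpoints."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "discrete_columns": list(self.discrete_columns),
            "continuous_columns": list(self.continuous_columns),
            "treatment_column": self.treatment_column,
            "outcome_column": self.outcome_column,
            "race_column": self.race_column,
            "aberration_expression_map": {
                k: list(v) for k, v in self.aberration_expression_map.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            discrete_columns=tuple(doc["discrete_columns"]),
            continuous_columns=tuple(doc["continuous_columns"]),
            treatment_column=doc["treatment_column"],
            outcome_column=doc["outcome_column"],
            race_column=doc["race_column"],
            aberration_expression_map={
                k: tuple(v) for k, v in doc.get("aberration_expression_map", {}).items()
            },
        )


def exclude_intervention_expression(schema: FeatureSchema, aberration: str) -> FeatureSchema:
    """Drop the intervention gene's own expression columns from x2.

    When an aberration of gene g is the intervention, g's expression would
    leak the treatment into the proxies; its expression columns are removed
    from the continuous block before inference.
    """
    if aberration not in schema.aberration_expression_map:
        known = sorted(schema.aberration_expression_map)
        raise KeyError(f"unknown aberration {aberration!r}; known aberrations: {known}")
    drop = set(schema.aberration_expression_map[aberration])
    return dataclasses.replace(
        schema,
        continuous_columns=tuple(c for c in schema.continuous_columns if c not in drop),
        aberration_expression_map={
            k: tuple(c for c in v if c not in drop)
            for k, v in schema.aberration_expression_map.items()
        },
    )


def schema_for_aberration(schema: FeatureSchema, aberration: str) -> FeatureSchema:
    """Re-target a multi-aberration schema so ``aberration`` is the treatment.

    The aberration column is moved out of the discrete proxies into the
    treatment slot (the previous treatment column, if it is an aberration
    itself, moves back into the proxies), then the expression-exclusion rule
    is applied.
    """
    if aberration == schema.treatment_column:
        return exclude_intervention_expression(schema, aberration)
    if aberration not in schema.discrete_columns:
        raise KeyError(
            f"{aberration!r} is not a discrete column; candidates: "
            f"{sorted(schema.aberration_expression_map)}"
        )
    discrete = [c for c in schema.discrete_columns if c != aberration]
    if schema.treatment_column in schema.aberration_expression_map:
        discrete.append(schema.treatment_column)
    out = dataclasses.replace(
        schema, discrete_columns=tuple(discrete), treatment_column=aberration
    )
    return exclude_intervention_expression(out, aberration)


# -- grade strata ---------------------------------------------------------

GRADE_LABELS = ("low", "intermediate", "high")


def grade_stratum(gs: int) -> str:
    """Map a Gleason Score to its clinical risk stratum.

    GS <= 6 is low-risk/non-aggressive disease, GS = 7 intermediate, and
    GS >= 8 high-risk/aggressive.
    """
    gs_int = int(gs)
    if gs_int != gs or not (GS_MIN <= gs_int <= GS_MAX):
        raise CohortValidationError(
            f"Gleason Score must be an integer in [{GS_MIN}, {GS_MAX}], got {gs!r}"
        )
    if gs_int <= 6:
        return "low"
    if gs_int == 7:
        return "intermediate"
    return "high"


def grade_strata(gs_values) -> np.ndarray:
    """Vectorized :func:`grade_stratum`."""
    return np.array([grade_stratum(g) for g in np.asarray(gs_values)])


# -- cohort table ---------------------------------------------------------

def normalize_race(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    text = str(value).strip()
    if text in RACE_LEVELS:
        return text
    return _RACE_SYNONYMS.get(text.lower(), "unknown")


@dataclass
class CohortTable:
    """A validated patient table bound to its :class:`FeatureSchema`.

    ``frame`` holds one row per patient in original order; a truth block
    (``y0_true``/``y1_true`` integer potential outcomes, optionally
    ``y0_latent``/``y1_latent`` on the pre-discretization continuous scale)
    is present only for synthetic cohorts.
    """

    schema: FeatureSchema
    frame: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def treatment(self) -> np.ndarray:
        return self.frame[self.schema.treatment_column].to_numpy(dtype=int)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame[self.schema.outcome_column].to_numpy(dtype=int)

    @property
    def race(self) -> np.ndarray:
        return self.frame[self.schema.race_column].to_numpy(dtype=object)

    @property
    def has_truth(self) -> bool:
        return all(c in self.frame.columns for c in TRUTH_COLUMNS)

    def grade(self) -> np.ndarray:
        return grade_strata(self.outcome)

    def subset(self, indices) -> "CohortTable":
        """Row subset (positional), preserving order of ``indices``."""
        return CohortTable(self.schema, self.frame.iloc[np.asarray(indices)].reset_index(drop=True))

    def with_schema(self, schema: FeatureSchema) -> "CohortTable":
        return CohortTable(schema, self.frame)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        s = self.schema
        missing = [c for c in s.all_columns if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort is missing schema column(s): {missing}")

        t = self.frame[s.treatment_column]
        if t.isna().any():
            raise CohortValidationError(
                f"missing treatment at rows {list(np.flatnonzero(t.isna().to_numpy()))[:5]}"
            )
        bad_t = ~t.isin([0, 1])
        if bad_t.any():
            rows = list(np.flatnonzero(bad_t.to_numpy()))[:5]
            raise CohortValidationError(
                f"treatment {s.treatment_column!r} must be 0/1; bad rows {rows}"
            )

        y = self.frame[s.outcome_column]
        if y.isna().any():
            raise CohortValidationError("missing outcome values")
        y_num = pd.to_numeric(y, errors="coerce")
        if y_num.isna().any() or (y_num != y_num.round()).any():
            rows = list(np.flatnonzero((y_num.isna() | (y_num != y_num.round())).to_numpy()))[:5]
            raise CohortValidationError(f"outcome must be integer Gleason Scores; bad rows {rows}")
        if ((y_num < GS_MIN) | (y_num > GS_MAX)).any():
            raise CohortValidationError(
                f"outcome outside the Gleason range [{GS_MIN}, {GS_MAX}]"
            )
        self.frame[s.outcome_column] = y_num.astype(int)

        races = self.frame[s.race_column].map(normalize_race)
        n_unknown = int((races == "unknown").sum())
        if n_unknown:
            logger.info("%d row(s) with missing/unrecognized race flagged 'unknown'", n_unknown)
        self.frame[s.race_column] = races

        if self.has_truth:
            t_arr = t.to_numpy(dtype=int)
            chosen = np.where(
                t_arr == 1,
                self.frame["y1_true"].to_numpy(dtype=float),
                self.frame["y0_true"].to_numpy(dtype=float),
            )
            if not np.array_equal(chosen, self.frame[s.outcome_column].to_numpy(dtype=float)):
                raise CohortValidationError(
                    "truth block inconsistent: observed outcome must equal the "
                    "potential outcome selected by the treatment"
                )


def read_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a delimited cohort table and validate it against ``schema``.

    The delimiter is sniffed from the header line (tab if present, else
    comma).  Row order is preserved; categorical discrete columns stay as
    strings and are one-hot expanded lazily by the model layer.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return CohortTable(schema, frame)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as tab-separated text (lossless round-trip)."""
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
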