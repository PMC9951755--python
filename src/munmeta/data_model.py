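"""Treatment-mean data schema, unit conversions, and study-level splitting.

The unit of analysis throughout the package is the *treatment mean*: one
experimental group's average urinary nitrogen excretion (UN, g/d) together
with the covariates reported alongside it (milk urea nitrogen MUN in mg/dL,
body weight, dry matter intake, dietary crude protein and NDF) and the
standard error of that mean (SEm), which drives the observation weights in
every downstream regression.  Studies belong to exactly one of two diet-type
strata -- confinement total mixed rations (TMR) or fresh-forage/pasture
diets -- and all resampling (the train/test split) operates on whole
studies, never on individual treatment means.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DietType",
    "TreatmentRecord",
    "StudyTable",
    "SplitSpec",
    "SchemaError",
    "RowValidationError",
    "COLUMNS",
    "MANDATORY_COLUMNS",
    "MILK_UREA_MMOL_L_DIVISOR",
    "UREA_N_FRACTION",
    "CP_PER_N",
    "convert_milk_urea_to_mun",
    "cp_from_n_intake",
    "bw_from_dmi_fraction",
    "read_treatment_table",
    "stratified_split",
]

#: Divisor converting milk urea (mmol/L) to MUN (mg/dL), stored exactly as
#: published.  Numerically it is ~1/(6.006 * 0.467) (urea molar mass 60.06
#: g/mol; urea is 46.7% N) but the printed divisor is authoritative because
#: every downstream coefficient was produced with it.
MILK_UREA_MMOL_L_DIVISOR = 0.357
#: Nitrogen mass fraction of urea (46.7%); converts milk urea mg/dL to MUN mg/dL.
UREA_N_FRACTION = 0.467
#: Crude protein equals dietary nitrogen times 6.25.
CP_PER_N = 6.25


class SchemaError(ValueError):
    """A required column is missing or the column mapping is invalid."""


class RowValidationError(ValueError):
    """One or more rows violate the treatment-record invariants.

    Attributes
    ----------
    errors : list of (row_index, message)
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors[:20])
        extra = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{extra}")


class DietType(enum.Enum):
    """Diet-type stratum of a study: total mixed ration or fresh forage."""

    TMR = "TMR"
    PASTURE = "PASTURE"

    @classmethod
    def parse(cls, value) -> "DietType":
        if isinstance(value, DietType):
            return value
        key = str(value).strip().upper().replace("-", " ").replace("_", " ")
        if key in {"TMR", "TOTAL MIXED RATION", "CONFINEMENT"}:
            return cls.TMR
        if key in {"PASTURE", "FRESH FORAGE", "FORAGE", "FF", "GRASS", "FRESH FORAGE BASED"}:
            return cls.PASTURE
        raise ValueError(f"unknown diet type {value!r}; expected TMR or PASTURE")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical column name -> (description, unit, mandatory flag).
COLUMNS: Mapping[str, tuple[str, str, bool]] = {
    "study_id": ("study identifier (DOI string)", "-", True),
    "diet": ("diet type, TMR or PASTURE", "-", True),
    "un_gd": ("urinary nitrogen excretion", "g/d", True),
    "un_sem": ("standard error of the treatment-mean UN", "g/d", False),
    "mun_mgdl": ("milk urea nitrogen", "mg/dL", True),
    "bw_kg": ("body weight", "kg", True),
    "dmi_kg": ("dry matter intake", "kg/d", True),
    "cp_pct": ("dietary crude protein", "% of DM", True),
    "ndf_pct": ("dietary neutral detergent fiber", "% of DM", False),
    "n_intake_gd": ("nitrogen intake", "g/d", False),
    "milk_yield_kgd": ("milk yield", "kg/d", False),
    "dim_d": ("days in milk", "d", False),
}

MANDATORY_COLUMNS: tuple[str, ...] = tuple(k for k, v in COLUMNS.items() if v[2])
NUMERIC_COLUMNS: tuple[str, ...] = tuple(k for k in COLUMNS if k not in ("study_id", "diet"))


@dataclass(frozen=True)
class TreatmentRecord:
    """One literature treatment mean.

    Optional covariates that a source did not report are ``None`` (never 0);
    operations that need them raise instead of guessing.
    """

    study_id: str
    diet: DietType
    un_gd: float
    mun_mgdl: float
    bw_kg: float
    dmi_kg: float
    cp_pct: float
    un_sem: float | None = None
    ndf_pct: float | None = None
    n_intake_gd: float | None = None
    milk_yield_kgd: float | None = None
    dim_d: float | None = None

    def validate(self, require_sem: bool = False) -> list[str]:
        errs = []
        for name, lo in (("un_gd", 0.0), ("mun_mgdl", 0.0), ("bw_kg", 0.0), ("dmi_kg", 0.0)):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= lo:
                errs.append(f"{name} must be finite and > {lo:g}, got {v!r}")
        if self.cp_pct is None or not (0.0 < self.cp_pct < 100.0):
            errs.append(f"cp_pct must lie in (0, 100), got {self.cp_pct!r}")
        if require_sem and (self.un_sem is None or not self.un_sem > 0):
            errs.append(f"un_sem must be > 0 when weighting is requested, got {self.un_sem!r}")
        if self.un_sem is not None and not self.un_sem > 0:
            errs.append(f"un_sem must be > 0 if present, got {self.un_sem!r}")
        return errs


def _records_to_frame(records: Iterable[TreatmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in COLUMNS}
        d["diet"] = DietType.parse(d["diet"])
        rows.append(d)
    return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass
class StudyTable:
    """An ordered collection of treatment means with study bookkeeping.

    Wraps a :class:`pandas.DataFrame` with the canonical columns of
    :data:`COLUMNS`; the ``diet`` column holds :class:`DietType` values.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for c in COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        df["diet"] = df["diet"].map(DietType.parse)
        df["study_id"] = df["study_id"].astype(str)
        self.df = df[list(COLUMNS)].reset_index(drop=True)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[TreatmentRecord], provenance: str = "") -> "StudyTable":
        return cls(_records_to_frame(records), provenance=provenance)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def study_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["study_id"]))

    @property
    def n_studies(self) -> int:
        return self.df["study_id"].nunique()

    def records(self) -> list[TreatmentRecord]:
        out = []
        for _, row in self.df.iterrows():
            kw = {k: row[k] for k in COLUMNS}
            for k in NUMERIC_COLUMNS:
                if pd.isna(kw[k]):
                    kw[k] = None
            out.append(TreatmentRecord(**kw))
        return out

    def subset(self, diet: DietType) -> "StudyTable":
        return StudyTable(self.df[self.df["diet"] == diet].reset_index(drop=True),
                          provenance=self.provenance)

    def diet_of_study(self) -> dict[str, DietType]:
        return {s: g["diet"].iloc[0] for s, g in self.df.groupby("study_id", sort=False)}

    # -- invariants --------------------------------------------------------
    def validate(self, require_sem: bool = False) -> "StudyTable":
        errors: list[tuple[int, str]] = []
        for i, rec in enumerate(self.records()):
            for msg in rec.validate(require_sem=require_sem):
                errors.append((i, msg))
        multi = self.df.groupby("study_id")["diet"].nunique()
        for sid in multi[multi > 1].index:
            idx = int(self.df.index[self.df["study_id"] == sid][0])
            errors.append((idx, f"study {sid} carries more than one diet type"))
        if errors:
            raise RowValidationError(errors)
        return self

    def canonical_sort(self) -> "StudyTable":
        """Sort by (diet, study_id), keeping within-study row order.

        Fits on the canonical order are therefore permutation-stable.
        """
        df = self.df.copy()
        df["_diet_key"] = df["diet"].map(lambda d: d.value)
        df = df.sort_values(["_diet_key", "study_id"], kind="stable").drop(columns="_diet_key")
        return StudyTable(df.reset_index(drop=True), provenance=self.provenance)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, sep: str = ",") -> None:
        df = self.df.copy()
        df["diet"] = df["diet"].map(lambda d: d.value)
        df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# unit conversions and derived covariates
# ---------------------------------------------------------------------------

_UNIT_ALIASES = {
    "milk_urea_mmol_l": "milk_urea_mmol_l",
    "milk urea mmol/l": "milk_urea_mmol_l",
    "mmol/l": "milk_urea_mmol_l",
    "milk_urea_mg_dl": "milk_urea_mg_dl",
    "milk urea mg/dl": "milk_urea_mg_dl",
    "mun_mg_dl": "mun_mg_dl",
    "mun mg/dl": "mun_mg_dl",
    "mg/dl mun": "mun_mg_dl",
}


def convert_milk_urea_to_mun(value: float, unit: str) -> float:
    """Convert a milk-urea measurement to MUN in mg/dL.

    ``milk_urea_mmol_l`` values are divided by 0.357; ``milk_urea_mg_dl``
    values are multiplied by 0.467 (the N fraction of urea); ``mun_mg_dl``
    is the identity.
    """
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    key = _UNIT_ALIASES.get(str(unit).strip().lower())
    if key is None:
        raise ValueError(f"unknown milk-urea unit {unit!r}")
    if key == "milk_urea_mmol_l":
        return value / MILK_UREA_MMOL_L_DIVISOR
    if key == "milk_urea_mg_dl":
        return value * UREA_N_FRACTION
    return float(value)


def cp_from_n_intake(n_intake_gd: float, dmi_kg: float) -> float:
    """Dietary crude protein (% of DM) from N intake (g/d) and DMI (kg/d).

    CP mass is N x 6.25; the percentage is taken of total dry matter intake.
    """
    if not (n_intake_gd > 0 and dmi_kg > 0):
        raise ValueError("n_intake_gd and dmi_kg must both be > 0")
    return 100.0 * (n_intake_gd * CP_PER_N) / (dmi_kg * 1000.0)


def bw_from_dmi_fraction(dmi_kg: float, dmi_pct_bw: float) -> float:
    """Body weight (kg) back-calculated from DMI reported as % of BW."""
    if not (dmi_kg > 0 and dmi_pct_bw > 0):
        raise ValueError("dmi_kg and dmi_pct_bw must both be > 0")
    return 100.0 * dmi_kg / dmi_pct_bw


# ---------------------------------------------------------------------------
# reading delimited tables
# ---------------------------------------------------------------------------

def read_treatment_table(path, schema: Mapping[str, str] | None = None,
                         require_sem: bool = False,
                         provenance: str | None = None) -> StudyTable:
    """Read a delimited text table of treatment means into a StudyTable.

    Parameters
    ----------
    path : str or path-like
        Comma- or tab-separated UTF-8 file with a header row.
    schema : mapping, optional
        Maps canonical column names (see :data:`COLUMNS`) to the column
        names used in the file.  Unmapped canonical names are looked up
        verbatim.
    require_sem : bool
        If True, rows without a positive ``un_sem`` are rejected (weighted
        analyses downstream need it).

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the error names it).
    RowValidationError
        For rows with unparsable numerics or invariant violations, with
        row-indexed diagnostics.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str,
                      skipinitialspace=True)
    raw.columns = [str(c).strip() for c in raw.columns]
    schema = dict(schema or {})
    rename = {}
    for canonical in COLUMNS:
        source = schema.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    df = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    errors: list[tuple[int, str]] = []
    for c in NUMERIC_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
            continue
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].notna() & df[c].astype(str).str.strip().ne("") & parsed.isna()
        for i in df.index[bad]:
            errors.append((int(i), f"unparsable numeric in column {c!r}: {df.at[i, c]!r}"))
        df[c] = parsed
    if errors:
        raise RowValidationError(errors)

    table = StudyTable(df[list(COLUMNS)],
                       provenance=provenance if provenance is not None else str(path))
    return table.validate(require_sem=require_sem)


# ---------------------------------------------------------------------------
# stratified train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """How to hold studies out: ``n_test_per_diet`` whole studies per stratum."""

    seed: int
    n_test_per_diet: int = 3


def stratified_split(table: StudyTable, spec: SplitSpec) -> tuple[StudyTable, StudyTable]:
    """Split a StudyTable into train/test sets by whole study, per diet.

    Exactly ``spec.n_test_per_diet`` studies from each diet stratum go to
    the test set; train and test never share a study.  Deterministic for a
    fixed seed regardless of input row order.
    """
    rng = np.random.default_rng(spec.seed)
    diet_map = table.diet_of_study()
    test_ids: set[str] = set()
    for diet in DietType:
        ids = sorted(s for s, d in diet_map.items() if d is diet)
        if spec.n_test_per_diet == 0:
            continue
        if len(ids) <= spec.n_test_per_diet:
            raise ValueError(
                f"stratum {diet.value} has {len(ids)} studies; "
                f"need more than n_test_per_diet={spec.n_test_per_diet}")
        chosen = rng.choice(len(ids), size=spec.n_test_per_diet, replace=False)
        test_ids.update(ids[i] for i in chosen)
    mask = table.df["study_id"].isin(test_ids)
    train = StudyTable(table.df[~mask].reset_index(drop=True), provenance=table.provenance)
    test = StudyTable(table.df[mask].reset_index(drop=True), provenance=table.provenance)
    return train, test
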