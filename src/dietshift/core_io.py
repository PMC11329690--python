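"""Typed tabular data model: schemas, validated readers/writers, consistency checks.

All pipeline inputs are delimiter-separated text with a header row, UTF-8,
``.`` decimal separator.  Tables are held as :class:`pandas.DataFrame` indexed
by their identifier column; validation is performed at load time so that
downstream stages can assume the declared invariants.

Wide tables (person x food intakes, person x nutrient intakes) carry one
column per food/nutrient; fixed-schema tables (persons, foods, impact
factors, trade records) declare their columns explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "FOOD_GROUPS",
    "IMPACT_COLS",
    "IMPACT_UNITS",
    "ColumnSpec",
    "TableSchema",
    "FOODS_SCHEMA",
    "PERSON_SCHEMA",
    "IMPACT_FACTOR_SCHEMA",
    "TRADE_SCHEMA",
    "INTAKE_SCHEMA",
    "NUTRIENT_SCHEMA",
    "read_table",
    "write_table",
    "read_impact_factors",
    "ConsistencyReport",
    "join_consistency_check",
    "write_report_tables",
]


class SchemaError(ValueError):
    """A table does not have the declared structure (missing/ill-typed columns)."""


class ValidationError(ValueError):
    """A table violates a declared value invariant."""


#: The ~25 ingredient-level food groups used throughout the pipeline.
FOOD_GROUPS: tuple[str, ...] = (
    "Fruits and berries",
    "Vegetables",
    "Potatoes",
    "Legumes",
    "Nuts and seeds",
    "Whole-grain cereals",
    "Refined grains",
    "Beef",
    "Pork",
    "Poultry",
    "Processed meat",
    "Fish",
    "Eggs",
    "Low-fat milk",
    "Liquid dairy",
    "Solid dairy",
    "Vegetable-based fat",
    "Animal fat",
    "Sweets and chocolate",
    "Sugared beverages",
    "Juices",
    "Alcoholic beverages",
    "Coffee and tea",
    "Condiments",
    "Other",
)

#: ReCiPe Midpoint (H) impact categories carried through the pipeline.
#: Factor tables store them per gram of food; per-person daily impacts
#: report the eutrophication categories in g/day (see :mod:`dietshift.footprint`).
IMPACT_COLS: tuple[str, ...] = ("gwp", "land_use", "marine_eutroph", "freshwater_eutroph")

IMPACT_UNITS: dict[str, str] = {
    "gwp": "kg CO2-eq",
    "land_use": "m2 annual-crop-eq",
    "marine_eutroph": "kg N-eq",
    "freshwater_eutroph": "kg P-eq",
}

MISSING = "missing"


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str = "float"  # float | int | str
    required: bool = True
    min: float | None = None
    max: float | None = None
    min_exclusive: bool = False
    allowed: tuple | None = None
    allow_missing: bool = False


@dataclass(frozen=True)
class TableSchema:
    name: str
    id_col: str
    columns: tuple[ColumnSpec, ...] = ()
    wide: bool = False          # every non-declared column is a numeric value column
    wide_min: float | None = None
    checks: tuple[Callable[[pd.DataFrame], None], ...] = ()


def _check_energy(df: pd.DataFrame) -> None:
    if "energy_kj" not in df.columns:
        raise SchemaError("nutrient table missing mandatory column 'energy_kj'")
    if (df["energy_kj"] <= 0).any():
        bad = df.index[df["energy_kj"] <= 0].tolist()
        raise ValidationError(f"energy_kj must be > 0 for every person; violated for {bad[:5]}")


def _check_protein_split(df: pd.DataFrame) -> None:
    cols = {"protein_g", "plant_protein_g", "animal_protein_g"}
    if cols.issubset(df.columns):
        tot = df["plant_protein_g"] + df["animal_protein_g"]
        if (tot > df["protein_g"] * (1 + 1e-6) + 1e-9).any():
            raise ValidationError("plant + animal protein exceeds total protein")


FOODS_SCHEMA = TableSchema(
    name="foods",
    id_col="food_id",
    columns=(
        ColumnSpec("name", kind="str"),
        ColumnSpec("food_group", kind="str", allowed=FOOD_GROUPS),
    ),
)

PERSON_SCHEMA = TableSchema(
    name="persons",
    id_col="person_id",
    columns=(
        ColumnSpec("sex", kind="str", allowed=("male", "female"), allow_missing=True),
        ColumnSpec("age", min=0, max=120),
        ColumnSpec("education", kind="int", min=1, max=3, allow_missing=True),
        ColumnSpec("income", kind="int", min=1, max=10, allow_missing=True),
        ColumnSpec("municipality", kind="str", allowed=("urban", "semi-urban", "rural"),
                   allow_missing=True),
        ColumnSpec("smoking", kind="int", min=1, max=4, allow_missing=True),
        ColumnSpec("physical_activity", kind="int", min=1, max=4, allow_missing=True),
        ColumnSpec("bmi", min=5, max=100),
        ColumnSpec("waist", min=20, max=250, required=False),
        ColumnSpec("survey_weight", min=0, min_exclusive=True),
    ),
)

IMPACT_FACTOR_SCHEMA = TableSchema(
    name="impact_factors",
    id_col="food_id",
    columns=tuple(ColumnSpec(c, min=0) for c in IMPACT_COLS)
    + (
        ColumnSpec("origin_flag", kind="str", allowed=("domestic", "imported"), required=False),
        ColumnSpec("adapted", kind="int", min=0, max=1, required=False),
    ),
)

TRADE_SCHEMA = TableSchema(
    name="trade",
    id_col="food_id",
    columns=(
        ColumnSpec("import_t", min=0),
        ColumnSpec("export_t", min=0),
    ),
)

INTAKE_SCHEMA = TableSchema(name="intakes", id_col="person_id", wide=True, wide_min=0.0)

NUTRIENT_SCHEMA = TableSchema(
    name="nutrients",
    id_col="person_id",
    wide=True,
    checks=(_check_energy, _check_protein_split),
)


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    return ","


def read_table(path, schema: TableSchema, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a delimiter-separated table against ``schema``.

    Returns a DataFrame indexed by the schema's identifier column.  Unknown
    columns (for fixed-schema tables) are preserved and listed in
    ``df.attrs["unknown_columns"]``.

    Raises
    ------
    SchemaError
        Mandatory column missing.
    ValidationError
        A cell cannot be parsed or violates a declared invariant; the message
        names the offending column and row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep or _sniff_sep(path), dtype=str,
                     keep_default_na=True, na_values=[""])
    return validate_table(df, schema)


def validate_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Coerce a raw (string-typed or mixed) DataFrame to ``schema`` and validate it."""
    df = df.copy()
    if schema.id_col in df.columns:
        df = df.set_index(schema.id_col)
    elif df.index.name != schema.id_col:
        raise SchemaError(f"{schema.name}: missing mandatory column '{schema.id_col}'")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{schema.name}: duplicate {schema.id_col} values {dups[:5]}")

    declared = {c.name for c in schema.columns}
    unknown: list[str] = []

    for col in schema.columns:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{schema.name}: missing mandatory column '{col.name}'")
            continue
        df[col.name] = _coerce_column(df[col.name], col, schema.name)

    if schema.wide:
        value_cols = [c for c in df.columns if c not in declared]
        for name in value_cols:
            spec = ColumnSpec(name, kind="float", min=schema.wide_min)
            df[name] = _coerce_column(df[name], spec, schema.name)
    else:
        unknown = [c for c in df.columns if c not in declared]

    for check in schema.checks:
        check(df)

    df.attrs["schema"] = schema.name
    df.attrs["unknown_columns"] = unknown
    return df


def _coerce_column(s: pd.Series, spec: ColumnSpec, table: str) -> pd.Series:
    label = f"{table}.{spec.name}"
    if spec.kind == "str":
        out = s.astype(object).where(~s.isna(), MISSING if spec.allow_missing else np.nan)
        if not spec.allow_missing and out.isna().any():
            row = out.index[out.isna()][0]
            raise ValidationError(f"{label}: missing value at row {row!r}")
        out = out.astype(str)
        if spec.allowed is not None:
            allowed = set(spec.allowed) | ({MISSING} if spec.allow_missing else set())
            bad = ~out.isin(allowed)
            if bad.any():
                row = out.index[bad][0]
                raise ValidationError(
                    f"{label}: value {out[bad].iloc[0]!r} at row {row!r} not in {sorted(allowed)}")
        return out

    num = pd.to_numeric(s, errors="coerce")
    unparsable = num.isna() & s.notna()
    if unparsable.any():
        row = s.index[unparsable][0]
        raise ValidationError(f"{label}: unparsable cell {s[unparsable].iloc[0]!r} at row {row!r}")
    if num.isna().any() and not spec.allow_missing:
        row = num.index[num.isna()][0]
        raise ValidationError(f"{label}: missing value at row {row!r}")
    if spec.min is not None:
        viol = (num < spec.min) | ((num == spec.min) if spec.min_exclusive else False)
        if viol.fillna(False).any():
            row = num.index[viol.fillna(False)][0]
            raise ValidationError(
                f"{label}: value {num[viol.fillna(False)].iloc[0]} at row {row!r} below "
                f"minimum {spec.min}{' (exclusive)' if spec.min_exclusive else ''}")
    if spec.max is not None:
        viol = (num > spec.max).fillna(False)
        if viol.any():
            row = num.index[viol][0]
            raise ValidationError(
                f"{label}: value {num[viol].iloc[0]} at row {row!r} above maximum {spec.max}")
    if spec.kind == "int":
        frac = num.dropna() % 1 != 0
        if frac.any():
            row = frac.index[frac][0]
            raise ValidationError(f"{label}: non-integer code at row {row!r}")
        return num.astype("Int64") if num.isna().any() else num.astype(int)
    return num.astype(float)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table losslessly (17 significant digits) with its index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.17g", lineterminator="\n")
    return path


def read_impact_factors(path, per: str = "g", sep: str | None = None) -> pd.DataFrame:
    """Read an impact-factor table, converting per-kg factors to per-gram.

    LCA sources report characterization results per kg of product while
    intakes are g/day; the pipeline stores factors per gram.  ``per='kg'``
    divides the four impact columns by 1000 and records the conversion in
    ``df.attrs["converted_from_per_kg"]``.
    """
    if per not in {"g", "kg"}:
        raise ValueError("per must be 'g' or 'kg'")
    df = read_table(path, IMPACT_FACTOR_SCHEMA, sep=sep)
    if per == "kg":
        df[list(IMPACT_COLS)] = df[list(IMPACT_COLS)] / 1000.0
        df.attrs["converted_from_per_kg"] = True
    else:
        df.attrs["converted_from_per_kg"] = False
    return df


@dataclass
class ConsistencyReport:
    """Cross-table identifier reconciliation for a loaded pipeline input set."""

    persons_without_attributes: list[str] = field(default_factory=list)
    persons_without_intakes: list[str] = field(default_factory=list)
    foods_without_factors: list[str] = field(default_factory=list)
    factors_without_foods: list[str] = field(default_factory=list)
    intake_foods_not_in_registry: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(getattr(self, f) for f in self.__dataclass_fields__)

    def to_json(self) -> str:
        return json.dumps({f: getattr(self, f) for f in self.__dataclass_fields__}, indent=2)


def join_consistency_check(
    intakes: pd.DataFrame,
    persons: pd.DataFrame,
    factors: pd.DataFrame,
    foods: pd.DataFrame,
) -> ConsistencyReport:
    """Reconcile identifiers across the four core inputs.

    Raises :class:`ValidationError` if the intake and person tables share no
    person_id at all (nothing downstream could run); everything else is
    reported for the caller to act on.  The footprint stage refuses to
    proceed on foods without factors unless told to drop them.
    """
    inter = intakes.index.intersection(persons.index)
    if len(inter) == 0:
        raise ValidationError("intake and person tables share no person_id")
    rep = ConsistencyReport()
    rep.persons_without_attributes = sorted(intakes.index.difference(persons.index))
    rep.persons_without_intakes = sorted(persons.index.difference(intakes.index))
    food_ids = pd.Index(foods.index)
    intake_foods = pd.Index(intakes.columns)
    rep.intake_foods_not_in_registry = sorted(intake_foods.difference(food_ids))
    rep.foods_without_factors = sorted(food_ids.difference(factors.index))
    rep.factors_without_foods = sorted(pd.Index(factors.index).difference(food_ids))
    return rep


def _format_float(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def write_report_tables(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Render summary tables with fixed decimal formatting.

    Means and other quantities are printed with 2 decimals; columns whose
    name contains ``v_test`` (or equals ``v``) with 4.  Column order is
    preserved, rows are sorted by index, so identical results always yield
    byte-identical files.
    """
    if not results:
        raise ValueError("no clusters: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        if df is None or len(df) == 0:
            raise ValueError(f"no clusters: result table '{name}' is empty")
        fmt = df.sort_index().copy()
        for col in fmt.columns:
            if pd.api.types.is_float_dtype(fmt[col]):
                decimals = 4 if ("v_test" in str(col) or str(col) == "v") else 2
                fmt[col] = fmt[col].map(lambda x, d=decimals: _format_float(x, d))
        path = out_dir / f"{name}.csv"
        fmt.to_csv(path, lineterminator="\n")
        written.append(path)
    return written
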