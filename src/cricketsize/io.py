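"""Reading, validation and writing of morphometric and calibration tables.

The individual-level table is a plain CSV (UTF-8, comma separated, header
row, decimal point) with one row per measured adult. Canonical columns are
``individual_id, site, isolation, origin, sex, year, instrument`` plus the
trait lengths in mm (``femur, wing, pronotum, genital``); a ``schema_map``
translates arbitrary file headers onto these names so deposited data with
different headers can be read unchanged. Missing trait cells (empty or
``NA``) stay missing. Validation is total: every row is either accepted or
reported with a row-level diagnostic; nothing is silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ISOLATION_LEVELS, ORIGINS, SEXES, INSTRUMENTS

TRAIT_COLUMNS = ["femur", "wing", "pronotum", "genital"]
FACTOR_COLUMNS = ["site", "isolation", "origin", "sex", "year", "instrument"]
REQUIRED_COLUMNS = ["site", "isolation", "origin", "sex", "year"]

# sanity bounds on any trait length: adult body length is 13-20 mm, so no
# single trait can plausibly reach 30 mm or be non-positive
TRAIT_MIN_MM = 0.0
TRAIT_MAX_MM = 30.0

_NA_STRINGS = {"", "na", "n/a", "nan", "none"}


class ValidationError(ValueError):
    """Raised when a table contains invalid rows; carries the diagnostics."""

    def __init__(self, diagnostics: list["RowDiagnostic"]):
        self.diagnostics = diagnostics
        preview = "; ".join(str(d) for d in diagnostics[:5])
        more = "" if len(diagnostics) <= 5 else f" (+{len(diagnostics) - 5} more)"
        super().__init__(f"{len(diagnostics)} invalid row(s): {preview}{more}")


@dataclass(frozen=True)
class RowDiagnostic:
    row: int            # 0-based data-row index in the file
    column: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}, column {self.column!r}: {self.message}"


def _apply_schema_map(df: pd.DataFrame, schema_map: dict | None) -> pd.DataFrame:
    if schema_map:
        df = df.rename(columns=schema_map)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _parse_trait(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        if value.strip().lower() in _NA_STRINGS:
            return np.nan
        return float(value)  # may raise ValueError
    return float(value)


def validate_morph_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Validate a raw morphometric frame; return (valid rows, diagnostics).

    Checks factor levels, year sanity, numeric trait cells and the
    0-30 mm length bound. Rows failing any check are excluded from the
    returned frame and reported; valid rows are returned with parsed
    numeric trait columns and missing cells preserved as NaN.
    """
    diags: list[RowDiagnostic] = []
    rows = []
    for i, rec in df.reset_index(drop=True).iterrows():
        ok = True
        out = dict(rec)
        for col, levels in (("isolation", ISOLATION_LEVELS), ("origin", ORIGINS),
                            ("sex", SEXES), ("instrument", INSTRUMENTS)):
            if col not in rec.index:
                continue
            val = str(rec[col]).strip().lower()
            if col == "instrument" and val in _NA_STRINGS:
                out[col] = np.nan
                continue
            if val not in levels:
                diags.append(RowDiagnostic(i, col, f"unknown level {rec[col]!r}"))
                ok = False
            else:
                out[col] = val
        try:
            year = int(rec["year"])
            if not (1900 < year < 2100):
                raise ValueError
            out["year"] = year
        except (ValueError, TypeError):
            diags.append(RowDiagnostic(i, "year", f"invalid year {rec['year']!r}"))
            ok = False
        for col in TRAIT_COLUMNS:
            if col not in rec.index:
                continue
            try:
                v = _parse_trait(rec[col])
            except (ValueError, TypeError):
                diags.append(RowDiagnostic(i, col, f"non-numeric value {rec[col]!r}"))
                ok = False
                continue
            if not np.isnan(v) and not (TRAIT_MIN_MM < v < TRAIT_MAX_MM):
                diags.append(RowDiagnostic(
                    i, col, f"length {v} mm outside ({TRAIT_MIN_MM}, {TRAIT_MAX_MM})"))
                ok = False
            out[col] = v
        if ok:
            rows.append(out)
    valid = pd.DataFrame(rows, columns=list(df.columns)) if rows else pd.DataFrame(columns=list(df.columns))
    return valid, diags


def infer_instrument(df: pd.DataFrame) -> pd.Series:
    """Instrument from the sampling design: field-2008 cohorts were measured
    with callipers, everything else (2010 field and laboratory) digitally."""
    is_calliper = (df["origin"] == "field") & (df["year"] == 2008)
    return pd.Series(np.where(is_calliper, "calliper", "digital"), index=df.index)


def read_morphometry_table(path, schema_map: dict | None = None,
                           on_invalid: str = "raise") -> pd.DataFrame:
    """Read and validate an individual-level morphometric CSV.

    Parameters
    ----------
    path
        CSV file path.
    schema_map
        Optional ``{file header -> canonical name}`` mapping.
    on_invalid
        ``"raise"`` (default) raises :class:`ValidationError` listing every
        bad row; ``"drop"`` returns the valid rows and attaches the
        diagnostics as ``df.attrs["diagnostics"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = _apply_schema_map(raw, schema_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"required column(s) not resolvable: {missing}")
    if "individual_id" not in raw.columns:
        raw["individual_id"] = [f"row{i:04d}" for i in range(len(raw))]
    valid, diags = validate_morph_records(raw)
    if diags and on_invalid == "raise":
        raise ValidationError(diags)
    if "instrument" not in valid.columns or valid["instrument"].isna().any():
        inferred = infer_instrument(valid)
        if "instrument" in valid.columns:
            valid["instrument"] = valid["instrument"].fillna(inferred)
        else:
            valid["instrument"] = inferred
    valid.attrs["diagnostics"] = diags
    return valid


def write_morphometry_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def read_calibration_table(path, schema_map: dict | None = None,
                           on_invalid: str = "raise") -> pd.DataFrame:
    """Read and validate a paired calliper/digital measurement CSV with
    columns ``individual_id, trait, calliper_mm, digital_mm``."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = _apply_schema_map(raw, schema_map)
    missing = [c for c in ("trait", "calliper_mm", "digital_mm")
               if c not in raw.columns]
    if missing:
        raise ValueError(f"required column(s) not resolvable: {missing}")
    diags: list[RowDiagnostic] = []
    rows = []
    for i, rec in raw.reset_index(drop=True).iterrows():
        ok = True
        out = dict(rec)
        for col in ("calliper_mm", "digital_mm"):
            try:
                v = float(rec[col])
            except (ValueError, TypeError):
                diags.append(RowDiagnostic(i, col, f"non-numeric value {rec[col]!r}"))
                ok = False
                continue
            if not (TRAIT_MIN_MM < v < TRAIT_MAX_MM):
                diags.append(RowDiagnostic(
                    i, col, f"length {v} mm outside ({TRAIT_MIN_MM}, {TRAIT_MAX_MM})"))
                ok = False
            out[col] = v
        if ok:
            rows.append(out)
    if diags and on_invalid == "raise":
        raise ValidationError(diags)
    valid = pd.DataFrame(rows, columns=list(raw.columns)) if rows else pd.DataFrame(columns=list(raw.columns))
    valid.attrs["diagnostics"] = diags
    return valid


def write_calibration_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def summarize_design(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell sample counts by site, origin-year cohort and sex.

    Returns a frame indexed by (site, cohort) with ``male``/``female``
    columns, cohorts being ``field-2008``, ``field-2010`` and
    ``laboratory-2010`` style labels. Empty input yields all-zero counts
    over the cells present (an empty frame)."""
    if records.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["site", "cohort"])
        return pd.DataFrame(columns=["male", "female"], index=idx)
    df = records.copy()
    df["cohort"] = df["origin"].astype(str) + "-" + df["year"].astype(int).astype(str)
    counts = (df.groupby(["site", "cohort", "sex"]).size()
                .unstack("sex", fill_value=0))
    for sex in ("male", "female"):
        if sex not in counts.columns:
            counts[sex] = 0
    return counts[["male", "female"]]


def design_summary_to_json(counts: pd.DataFrame, path) -> None:
    """Export the count summary as JSON keyed ``site/cohort/sex``."""
    payload: dict = {}
    for (site, cohort), row in counts.iterrows():
        payload.setdefault(site, {})[cohort] = {
            "male": int(row["male"]), "female": int(row["female"])}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
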