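"""Cohort CSV schema, validation and the per-eye pipeline.

The interchange format is a flat CSV, one row per eye, headers
case-insensitive:

    eye_id, axial_length_mm, k_mean_d, r_anterior_mm, r_posterior_mm,
    a_constant [, implanted_power_d, postop_se_d, target_refraction_d]

Units are carried in the header names (mm, diopters); decimal points only.
`run_pipeline` evaluates the ISS chain per eye in one of three modes:
``predict`` (predicted refraction for the implanted power), ``power``
(recommended IOL power for the target refraction) or ``evaluate``
(prediction errors plus a cohort summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cfactor import CFactorModel, DEFAULT_C_FACTOR, ap_ratio
from .optics import (
    EyeBiometry,
    LensConstants,
    OpticalConstants,
    SrktInternals,
    elp_estimate,
    iss_iol_power,
    iss_predicted_refraction,
    select_iol_power,
)
from .outcomes import OutcomeSummary, summarize

__all__ = ["CohortSchemaError", "read_cohort", "write_cohort", "run_pipeline",
           "PipelineResult"]

REQUIRED_COLUMNS = (
    "eye_id",
    "axial_length_mm",
    "k_mean_d",
    "r_anterior_mm",
    "r_posterior_mm",
    "a_constant",
)
OPTIONAL_COLUMNS = ("implanted_power_d", "postop_se_d", "target_refraction_d")
MODES = ("predict", "power", "evaluate")


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the CSV schema."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    numeric = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
               if c != "eye_id" and c in df.columns]
    bad_rows: list[str] = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            bad_rows.append(f"row {i + 2}: unparseable {col}={df.loc[i, col]!r}")
        df[col] = coerced
    if bad_rows:
        raise CohortSchemaError("numeric parse failures: " + "; ".join(bad_rows))
    nan_required = [c for c in numeric if c in REQUIRED_COLUMNS and df[c].isna().any()]
    if nan_required:
        raise CohortSchemaError(
            f"missing values in required column(s): {', '.join(nan_required)}"
        )
    dup = df["eye_id"].astype(str)[df["eye_id"].astype(str).duplicated()]
    if not dup.empty:
        raise CohortSchemaError(f"duplicate eye_id(s): {', '.join(dup.unique())}")
    df["eye_id"] = df["eye_id"].astype(str)
    return df.reset_index(drop=True)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending column or
    rows (1-based, counting the header)."""
    return _validate(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


@dataclass(frozen=True)
class PipelineResult:
    """Per-eye pipeline output plus, in evaluate mode, the cohort summary."""

    table: pd.DataFrame
    summary: OutcomeSummary | None = None


def run_pipeline(
    cohort: pd.DataFrame,
    model: CFactorModel = DEFAULT_C_FACTOR,
    mode: str = "predict",
    kpre_d: float | None = None,
    constants: OpticalConstants = OpticalConstants(),
    internals: SrktInternals = SrktInternals(),
    power_step_d: float = 0.5,
) -> PipelineResult:
    """Run the ISS chain over a validated cohort table.

    predict  : needs implanted_power_d; adds predicted refraction.
    power    : uses target_refraction_d (default 0); adds exact and rounded
               recommended power.
    evaluate : needs implanted_power_d and postop_se_d; adds prediction
               error and attaches an :class:`OutcomeSummary`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    cohort = _validate(cohort.copy())
    needs = {"predict": ("implanted_power_d",),
             "power": (),
             "evaluate": ("implanted_power_d", "postop_se_d")}[mode]
    for col in needs:
        if col not in cohort.columns or cohort[col].isna().any():
            raise CohortSchemaError(f"mode {mode!r} requires complete column {col!r}")

    out_rows = []
    for _, row in cohort.iterrows():
        eye = EyeBiometry(
            axial_length_mm=row["axial_length_mm"],
            kpost_d=row["k_mean_d"],
            r_anterior_mm=row["r_anterior_mm"],
            r_posterior_mm=row["r_posterior_mm"],
        )
        kpre = kpre_d if kpre_d is not None else constants.kpre_default_d
        ratio = ap_ratio(eye.r_anterior_mm, eye.r_posterior_mm)
        c = float(model.apply(ratio))
        elp = elp_estimate(kpre, eye.axial_length_mm, row["a_constant"],
                           constants, internals)
        rec: dict = {
            "eye_id": row["eye_id"],
            "ap_ratio": ratio,
            "c_factor_d": c,
            "acd_est_mm": elp.acd_est_mm,
        }
        if mode in ("predict", "evaluate"):
            lens = LensConstants(row["a_constant"],
                                 implanted_power_d=row["implanted_power_d"])
            pred = iss_predicted_refraction(eye, lens, c, kpre, constants, internals)
            rec["predicted_refraction_d"] = pred.predicted_refraction_d
            if mode == "evaluate":
                rec["actual_se_d"] = row["postop_se_d"]
                rec["error_d"] = row["postop_se_d"] - pred.predicted_refraction_d
        if mode == "power":
            target = row.get("target_refraction_d", 0.0)
            if pd.isna(target):
                target = 0.0
            exact = iss_iol_power(eye, float(target), c, row["a_constant"],
                                  kpre, constants, internals)
            rec["exact_power_d"] = exact
            rec["recommended_power_d"] = select_iol_power(exact, power_step_d)
        out_rows.append(rec)

    table = pd.DataFrame(out_rows)
    summary = summarize(table["error_d"].to_numpy()) if mode == "evaluate" else None
    return PipelineResult(table=table, summary=summary)
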