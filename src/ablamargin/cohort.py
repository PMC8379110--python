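"""Cohort records and the flat CSV schema shared by simulator and stats.

One row per treated tumor: margin profile (R, U_1..U_10), local tumor
progression (LTP) outcome with time-to-event, and the clinical
covariates used in univariate risk screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CohortRecord", "COHORT_COLUMNS", "cohort_to_frame", "frame_to_cohort",
           "read_cohort_csv", "write_cohort_csv", "CohortSchemaError"]


class CohortSchemaError(ValueError):
    """A cohort table is missing required columns or has bad values."""


#: binary / numeric covariates carried by every record
COVARIATE_COLUMNS = (
    "age",
    "male",
    "size_mm",
    "subcapsular",
    "vessel",
    "organ",
    "prior_ctx",
    "prior_hr",
    "adjuvant_ctx",
)

COHORT_COLUMNS = (
    "case_id",
    "ltp",
    "time_months",
    "residual_pct",
    *[f"u{m}" for m in range(1, 11)],
    *COVARIATE_COLUMNS,
)


@dataclass
class CohortRecord:
    """One tumor: margin assessment, LTP outcome and covariates."""

    case_id: str
    residual_pct: float
    unablated_pct_by_margin: dict[float, float]
    ltp: bool
    time_months: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise CohortSchemaError(
                f"time_months must be positive, got {self.time_months}"
            )

    @property
    def censored(self) -> bool:
        return not self.ltp

    def u(self, m: float) -> float:
        try:
            return self.unablated_pct_by_margin[float(m)]
        except KeyError:
            raise CohortSchemaError(
                f"case {self.case_id} has no unablated percentage at {m} mm"
            ) from None


def cohort_to_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records into the canonical cohort table."""
    rows = []
    for rec in cohort:
        row = {
            "case_id": rec.case_id,
            "ltp": int(rec.ltp),
            "time_months": rec.time_months,
            "residual_pct": rec.residual_pct,
        }
        for m in range(1, 11):
            row[f"u{m}"] = rec.unablated_pct_by_margin.get(float(m), float("nan"))
        for c in COVARIATE_COLUMNS:
            row[c] = rec.covariates.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[CohortRecord]:
    """Parse the canonical cohort table back into records."""
    required = {"case_id", "ltp", "time_months", "residual_pct"}
    required |= {f"u{m}" for m in range(1, 11)}
    missing = sorted(required - set(df.columns))
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {', '.join(missing)}")
    cohort = []
    # iterrows() would upcast mixed rows to float and mangle string ids
    case_ids = df["case_id"].astype(str).to_list()
    for case_id, (_, row) in zip(case_ids, df.iterrows()):
        cohort.append(
            CohortRecord(
                case_id=case_id,
                residual_pct=float(row["residual_pct"]),
                unablated_pct_by_margin={
                    float(m): float(row[f"u{m}"]) for m in range(1, 11)
                },
                ltp=bool(int(row["ltp"])),
                time_months=float(row["time_months"]),
                covariates={
                    c: float(row[c])
                    for c in COVARIATE_COLUMNS
                    if c in df.columns and pd.notna(row[c])
                },
            )
        )
    return cohort


def read_cohort_csv(path) -> list[CohortRecord]:
    return frame_to_cohort(pd.read_csv(path))


def write_cohort_csv(cohort: list[CohortRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
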