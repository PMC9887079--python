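"""Delimited-text cohort I/O.

The cohort format is a UTF-8 CSV with a header row and one row per scan:

    lesion_id, patient_id, time_months, volume_cm3 [, label, subgroup, upfront_wbrt]

Rows are grouped by lesion and sorted by time on read.  Times are re-based
to months since each lesion's first scan (the model is time-translation
invariant and absolute dates are identifying).  Volumes are cm^3 internally;
``units="mm3"`` converts on read.  Lesions failing the three-increasing-point
inclusion criterion are loaded but remain ineligible for fitting (see
``LesionSeries.eligible``) rather than raising.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fitting import LesionSeries
from .simulate import SyntheticLesion

__all__ = ["CohortFormatError", "read_cohort", "write_cohort", "write_truth"]

REQUIRED_COLUMNS = ("lesion_id", "patient_id", "time_months", "volume_cm3")
OPTIONAL_COLUMNS = ("label", "subgroup", "upfront_wbrt")


class CohortFormatError(ValueError):
    """Malformed cohort table; carries per-row diagnostics."""

    def __init__(self, problems: list):
        self.problems = list(problems)
        super().__init__(
            "cohort table has {} problem(s):\n  {}".format(
                len(self.problems), "\n  ".join(self.problems)
            )
        )


def _parse_bool(value) -> bool | None:
    if pd.isna(value) or value == "":
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_cohort(
    path, units: str = "cm3", on_error: str = "raise"
) -> list[LesionSeries]:
    """Load a cohort CSV into a list of :class:`LesionSeries`.

    Parameters
    ----------
    path:
        CSV file with the columns documented in the module header.
    units:
        "cm3" (default) or "mm3"; mm^3 volumes are divided by 1000 on read
        so the pipeline runs on a single internal unit.
    on_error:
        "raise" (default) raises :class:`CohortFormatError` listing every
        per-row problem; "skip" drops offending lesions with a warning.
    """
    if units not in ("cm3", "mm3"):
        raise ValueError(f"units must be 'cm3' or 'mm3', got {units!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    table = pd.read_csv(
        path,
        dtype={"lesion_id": str, "patient_id": str},
        float_precision="round_trip",  # lossless write->read->write cycles
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError([f"missing required column(s): {', '.join(missing)}"])
    if units == "mm3":
        table = table.assign(volume_cm3=table["volume_cm3"] / 1000.0)

    problems: list[str] = []
    bad_lesions: set = set()
    dup = table.duplicated(subset=["lesion_id", "time_months"], keep=False)
    for _, row in table[dup].drop_duplicates(["lesion_id", "time_months"]).iterrows():
        problems.append(
            f"lesion {row['lesion_id']}: duplicate time {row['time_months']}"
        )
        bad_lesions.add(row["lesion_id"])
    for _, row in table[table["volume_cm3"] <= 0].iterrows():
        problems.append(
            f"lesion {row['lesion_id']}: non-positive volume {row['volume_cm3']}"
        )
        bad_lesions.add(row["lesion_id"])
    if problems:
        if on_error == "raise":
            raise CohortFormatError(problems)
        warnings.warn(
            "skipping {} malformed lesion(s): {}".format(
                len(bad_lesions), "; ".join(problems)
            )
        )
        table = table[~table["lesion_id"].isin(bad_lesions)]

    series_list: list[LesionSeries] = []
    for lesion_id, grp in table.groupby("lesion_id", sort=True):
        grp = grp.sort_values("time_months")
        t0 = float(grp["time_months"].iloc[0])
        first = grp.iloc[0]
        label = "unknown"
        if "label" in grp.columns and not pd.isna(first.get("label")):
            label = str(first["label"])
        subgroup = None
        if "subgroup" in grp.columns and not pd.isna(first.get("subgroup")):
            subgroup = str(first["subgroup"])
        wbrt = None
        if "upfront_wbrt" in grp.columns:
            wbrt = _parse_bool(first.get("upfront_wbrt"))
        series_list.append(
            LesionSeries(
                lesion_id=str(lesion_id),
                patient_id=str(first["patient_id"]),
                times=tuple(float(t) - t0 for t in grp["time_months"]),
                volumes=tuple(float(v) for v in grp["volume_cm3"]),
                label=label,
                subgroup=subgroup,
                upfront_wbrt=wbrt,
            )
        )
    return series_list


def _series_frame(series_list: Sequence[LesionSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.volumes):
            rows.append(
                {
                    "lesion_id": s.lesion_id,
                    "patient_id": s.patient_id,
                    "time_months": t,
                    "volume_cm3": v,
                    "label": s.label,
                    "subgroup": "" if s.subgroup is None else s.subgroup,
                    "upfront_wbrt": "" if s.upfront_wbrt is None else s.upfront_wbrt,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(series_list: Sequence[LesionSeries], path) -> None:
    """Write lesion series to the cohort CSV format (round-trip safe)."""
    _series_frame(series_list).to_csv(path, index=False)


def write_truth(cohort: Sequence[SyntheticLesion], path) -> None:
    """Write the generator's ground truth to a separate table.

    Kept apart from the observable cohort so the truth can never leak into
    an analysis by accident.
    """
    rows = [
        {
            "lesion_id": lesion.series.lesion_id,
            "true_v0": lesion.true_params.v0,
            "true_alpha": lesion.true_params.alpha,
            "true_beta": lesion.true_params.beta,
            "true_lambda1": lesion.true_lambda.lambda1,
            "true_lambda2": lesion.true_lambda.lambda2,
        }
        for lesion in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
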