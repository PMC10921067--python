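"""Reading and writing the delimited-text formats used between stages.

Cohort files are UTF-8 delimited text (comma by default, tab accepted),
one row per participant:

    participant_id, group, sex, education, baseline_age, followup_years,
    diagnosis_age, <test>_baseline, <test>_t2, ...

Missing values (e.g. diagnosis_age for controls) are empty fields, never
zeros. Unknown columns round-trip through ``ParticipantRecord.extras``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError
from .synthetic import ParticipantRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_bands",
    "write_changes",
    "read_changes",
    "read_bands",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "group",
    "sex",
    "education",
    "baseline_age",
    "followup_years",
    "diagnosis_age",
)


def _test_names(records: Sequence[ParticipantRecord]) -> list[str]:
    names: list[str] = []
    for rec in records:
        for name in rec.scores:
            if name not in names:
                names.append(name)
    return names


def write_cohort(records: Sequence[ParticipantRecord], path, sep: str = ",") -> None:
    """Write one row per participant; round-trips losslessly with read_cohort."""
    if not records:
        raise ValueError("cannot write an empty cohort")
    tests = _test_names(records)
    rows = []
    for rec in records:
        row = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "sex": rec.sex,
            "education": rec.education,
            "baseline_age": repr(rec.baseline_age),
            "followup_years": repr(rec.followup_years),
            "diagnosis_age": "" if rec.diagnosis_age is None else repr(rec.diagnosis_age),
        }
        for t in tests:
            b, t2 = rec.scores.get(t, (None, None))
            row[f"{t}_baseline"] = "" if b is None else repr(b)
            row[f"{t}_t2"] = "" if t2 is None else repr(t2)
        row.update({k: str(v) for k, v in rec.extras.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path) -> list[ParticipantRecord]:
    """Parse a cohort file into typed records.

    Raises SchemaError naming any missing required column, and reports
    malformed (non-numeric) rows with their 1-based file line numbers.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    cols = list(df.columns)
    test_names = sorted(
        {
            c[: -len("_baseline")]
            for c in cols
            if c.endswith("_baseline") and f"{c[:-len('_baseline')]}_t2" in cols
        },
        key=lambda t: cols.index(f"{t}_baseline"),
    )
    score_cols = {f"{t}_baseline" for t in test_names} | {f"{t}_t2" for t in test_names}
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS and c not in score_cols]

    records: list[ParticipantRecord] = []
    bad_lines: list[str] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            baseline_age = float(row["baseline_age"])
            followup = float(row["followup_years"])
            diagnosis = None if row["diagnosis_age"] == "" else float(row["diagnosis_age"])
            scores = {}
            for t in test_names:
                b, t2 = row[f"{t}_baseline"], row[f"{t}_t2"]
                if b == "" or t2 == "":
                    continue
                scores[t] = (float(b), float(t2))
        except ValueError as exc:
            bad_lines.append(f"line {line_no}: {exc}")
            continue
        if not (math.isfinite(baseline_age) and math.isfinite(followup)):
            bad_lines.append(f"line {line_no}: non-finite age or follow-up")
            continue
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                baseline_age=baseline_age,
                followup_years=followup,
                diagnosis_age=diagnosis,
                sex=str(row["sex"]),
                education=str(row["education"]),
                scores=scores,
                extras={c: row[c] for c in extra_cols},
            )
        )
    if bad_lines:
        raise SchemaError("malformed row(s): " + "; ".join(bad_lines))
    return records


def write_changes(changes: Iterable, path, sep: str = ",") -> None:
    """Change-score table: one row per (participant, test)."""
    rows = [
        {
            "participant_id": c.participant_id,
            "group": c.group,
            "test_name": c.test_name,
            "baseline_age": c.baseline_age,
            "followup_years": c.followup_years,
            "raw_change": c.raw_change,
            "proportional_change": c.proportional_change,
        }
        for c in changes
    ]
    pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "test_name",
            "baseline_age",
            "followup_years",
            "raw_change",
            "proportional_change",
        ],
    ).to_csv(path, sep=sep, index=False)


def read_changes(path, sep: str | None = None):
    """Read a change-score table back into ChangeRecord objects."""
    from .prep import ChangeRecord

    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    return [
        ChangeRecord(
            participant_id=str(r.participant_id),
            group=str(r.group),
            test_name=str(r.test_name),
            baseline_age=float(r.baseline_age),
            followup_years=float(r.followup_years),
            raw_change=float(r.raw_change),
            proportional_change=float(r.proportional_change),
        )
        for r in df.itertuples(index=False)
    ]


def read_bands(path, sep: str | None = None):
    """Read a band-series table back into AgeBandSummary objects."""
    from .bands import AgeBandSummary

    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    return [
        AgeBandSummary(
            band_start=int(r.band_start),
            band_end=int(r.band_end),
            n_obs=int(r.n_obs),
            mean_prop_change=float(r.mean_prop_change),
            included=bool(r.included),
        )
        for r in df.itertuples(index=False)
    ]


def write_bands(bands: Iterable, path, sep: str = ",") -> None:
    """Band series: the exact input handed to the Emax fit."""
    rows = [
        {
            "band_start": b.band_start,
            "band_end": b.band_end,
            "n_obs": b.n_obs,
            "mean_prop_change": b.mean_prop_change,
            "included": b.included,
        }
        for b in bands
    ]
    pd.DataFrame(
        rows, columns=["band_start", "band_end", "n_obs", "mean_prop_change", "included"]
    ).to_csv(path, sep=sep, index=False)
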