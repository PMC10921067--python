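"""Eligibility filtering and per-participant change scores.

The analysis window keeps participants whose follow-up fell 3 to 4 years
(inclusive) after baseline, excludes prevalent baseline dementia, and
reduces each retained participant to a raw change (T2 - baseline, native
scale) and a proportional change ((T2 - baseline) / baseline). The
proportional change is sign-normalized so that decline is negative for
every instrument: for timed tests where a longer time is worse (Trail
Making Part B) the ratio is multiplied by -1. One sign convention lets a
single Emax code path serve all tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import SpecValidationError
from .synthetic import ParticipantRecord, TestSpec

__all__ = ["EligibilityRules", "ChangeRecord", "filter_eligible", "compute_changes"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EligibilityRules:
    """Closed follow-up window [min_followup, max_followup] in years."""

    min_followup: float = 3.0
    max_followup: float = 4.0
    exclude_baseline_dementia: bool = True

    def __post_init__(self) -> None:
        if not self.min_followup < self.max_followup:
            raise SpecValidationError("min_followup: must be below max_followup")


@dataclass(frozen=True)
class ChangeRecord:
    participant_id: str
    group: str
    test_name: str
    baseline_age: float
    followup_years: float
    raw_change: float
    proportional_change: float


def filter_eligible(
    records: list[ParticipantRecord], rules: EligibilityRules | None = None
) -> list[ParticipantRecord]:
    """Keep records inside the follow-up window and free of baseline dementia.

    Idempotent; per-rule exclusion counts go to the module log. A record
    carries a baseline dementia marker through its ``extras`` mapping
    (key ``baseline_dementia``, truthy values '1'/'true'/'yes').
    """
    if rules is None:
        rules = EligibilityRules()
    kept: list[ParticipantRecord] = []
    n_window = n_dementia = 0
    for rec in records:
        if not rules.min_followup <= rec.followup_years <= rules.max_followup:
            n_window += 1
            continue
        if rules.exclude_baseline_dementia and _has_baseline_dementia(rec):
            n_dementia += 1
            continue
        kept.append(rec)
    logger.info(
        "eligibility: kept %d of %d (excluded %d outside [%g, %g] y follow-up, "
        "%d prevalent baseline dementia)",
        len(kept), len(records), n_window,
        rules.min_followup, rules.max_followup, n_dementia,
    )
    return kept


def _has_baseline_dementia(rec: ParticipantRecord) -> bool:
    value = rec.extras.get("baseline_dementia", "")
    return str(value).strip().lower() in {"1", "true", "yes"}


def exclusion_counts(
    records: list[ParticipantRecord], rules: EligibilityRules | None = None
) -> dict[str, int]:
    """Reconciliation ledger: kept + excluded counts sum to the input size."""
    if rules is None:
        rules = EligibilityRules()
    counts = {"input": len(records), "kept": 0, "outside_window": 0, "baseline_dementia": 0}
    for rec in records:
        if not rules.min_followup <= rec.followup_years <= rules.max_followup:
            counts["outside_window"] += 1
        elif rules.exclude_baseline_dementia and _has_baseline_dementia(rec):
            counts["baseline_dementia"] += 1
        else:
            counts["kept"] += 1
    return counts


def compute_changes(
    records: list[ParticipantRecord], test: TestSpec
) -> list[ChangeRecord]:
    """Raw and sign-normalized proportional change for one instrument.

    Participants missing either score are skipped; a baseline score of
    exactly zero leaves the proportional change undefined and the record
    is dropped. Both exclusions are counted in the log, never fatal.
    """
    out: list[ChangeRecord] = []
    n_missing = n_zero = 0
    sign = 1.0 if test.direction == "higher_is_better" else -1.0
    for rec in records:
        pair = rec.scores.get(test.test_name)
        if pair is None or pair[0] is None or pair[1] is None:
            n_missing += 1
            continue
        baseline, t2 = pair
        if baseline == 0:
            n_zero += 1
            continue
        out.append(
            ChangeRecord(
                participant_id=rec.participant_id,
                group=rec.group,
                test_name=test.test_name,
                baseline_age=rec.baseline_age,
                followup_years=rec.followup_years,
                raw_change=t2 - baseline,
                proportional_change=sign * (t2 - baseline) / baseline,
            )
        )
    logger.info(
        "changes[%s]: %d computed, %d missing-score, %d zero-baseline",
        test.test_name, len(out), n_missing, n_zero,
    )
    return out
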