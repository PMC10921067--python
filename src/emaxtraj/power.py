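"""Hypothetical-RCT effect sizes and sample sizes from band change scores.

Raw changes observed over 3-4 years in a chosen baseline-age band stand
in for the placebo arm of a two-arm trial of a given duration; each
participant's change is rescaled linearly (duration / follow-up) before
averaging. A treatment of efficacy f is assumed to shrink the mean
change to (1 - f) times the placebo mean. Cohen's d then feeds an exact
two-sample t-test power calculation: the minimal per-group n is the
smallest integer whose noncentral-t power (df = 2n - 2, noncentrality
|d| * sqrt(n/2)) reaches the target at the chosen alpha and sidedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .prep import ChangeRecord

__all__ = [
    "PowerScenario",
    "PowerResult",
    "band_change_stats",
    "expected_treatment_change",
    "cohens_d",
    "power_two_sample_t",
    "required_n",
    "scenario_result",
    "power_report",
]


@dataclass(frozen=True)
class PowerScenario:
    efficacy: float
    alpha: float = 0.05
    power: float = 0.80
    sidedness: str = "one_sided"  # or "two_sided"
    trial_duration: float = 2.0
    allocation_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("efficacy", "alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass(frozen=True)
class PowerResult:
    control_mean_change: float
    pooled_sd: float
    treatment_mean_change: float
    cohens_d: float
    n_per_group: int
    n_total: int


def band_change_stats(
    changes: Sequence[ChangeRecord],
    band: tuple[int, int],
    duration: float,
) -> tuple[float, float]:
    """Mean and sample SD of duration-rescaled raw changes in one band.

    Band membership uses the same half-open window as the band series:
    baseline age in [start, end + 1) for the label (start, end). Each raw
    change is multiplied by duration / followup_years before averaging.
    """
    start, end = band
    members = [c for c in changes if start <= c.baseline_age < end + 1]
    if len(members) < 2:
        raise InsufficientDataError(
            f"band {start}-{end}: need >= 2 members, got {len(members)}"
        )
    rescaled = np.array(
        [c.raw_change * duration / c.followup_years for c in members], dtype=float
    )
    return float(rescaled.mean()), float(rescaled.std(ddof=1))


def expected_treatment_change(control_mean: float, efficacy: float) -> float:
    """Mean change in the treated arm when decline shrinks by ``efficacy``."""
    return control_mean * (1.0 - efficacy)


def cohens_d(control_mean: float, treatment_mean: float, pooled_sd: float) -> float:
    """Signed standardized difference (control - treatment) / pooled SD.

    With decline-negative change scores a partially effective treatment
    has the less negative mean, making d negative — the sign convention
    of these trial-planning tables. Only |d| enters the power search.
    """
    if pooled_sd <= 0:
        raise ValueError(f"pooled_sd must be > 0, got {pooled_sd}")
    return (control_mean - treatment_mean) / pooled_sd


def power_two_sample_t(
    n_per_group: int, d: float, alpha: float = 0.05, sidedness: str = "one_sided"
) -> float:
    """Exact power of the two-sample t-test at effect size d."""
    df = 2 * n_per_group - 2
    ncp = abs(d) * np.sqrt(n_per_group / 2.0)
    crit_p = 1.0 - (alpha if sidedness == "one_sided" else alpha / 2.0)
    tcrit = stats.t.ppf(crit_p, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def required_n(d: float, scenario: PowerScenario) -> tuple[int, int]:
    """Smallest per-group n reaching the target power; returns (n, 2n).

    Power is monotone in n, so an exponential bracket followed by integer
    bisection finds the minimum exactly even for tiny effects.
    """
    if d == 0:
        raise ValueError("d = 0 has no finite sample size")

    def achieved(n):
        return power_two_sample_t(n, d, scenario.alpha, scenario.sidedness)

    hi = 2
    while achieved(hi) < scenario.power:
        hi *= 2
        if hi > 1 << 40:  # pragma: no cover - unreachable for d != 0
            raise ValueError("no attainable sample size")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= scenario.power:
            hi = mid
        else:
            lo = mid + 1
    return hi, 2 * hi


def scenario_result(
    control_mean: float,
    pooled_sd: float,
    scenario: PowerScenario,
    round_d: bool = False,
) -> PowerResult:
    """Full chain: treatment mean -> d -> minimal sample size.

    By default d is carried at full precision into the sample-size
    search, the way a power calculator uses means and SD entered through
    its effect-size drawer while displaying d rounded to two decimals.
    ``round_d=True`` instead feeds the two-decimal d itself, for users
    reproducing a calculation whose only record is the printed d.
    """
    treatment_mean = expected_treatment_change(control_mean, scenario.efficacy)
    d = cohens_d(control_mean, treatment_mean, pooled_sd)
    d_for_n = round(d, 2) if round_d else d
    n_per_group, n_total = required_n(d_for_n, scenario)
    return PowerResult(
        control_mean_change=control_mean,
        pooled_sd=pooled_sd,
        treatment_mean_change=treatment_mean,
        cohens_d=d,
        n_per_group=n_per_group,
        n_total=n_total,
    )


def power_report(
    band_stats: dict[tuple[str, tuple[int, int]], tuple[float, float]],
    scenarios: Sequence[PowerScenario],
    round_d: bool = False,
):
    """One row per (test, band) with per-scenario treatment mean, d, total N."""
    import pandas as pd

    rows = []
    for (test, band), (mean, sd) in band_stats.items():
        row: dict = {
            "test": test,
            "band": f"{band[0]}–{band[1]}",
            "control_mean_change": round(mean, 2),
            "pooled_sd": round(sd, 2),
        }
        for sc in scenarios:
            res = scenario_result(mean, sd, sc, round_d=round_d)
            tag = f"{sc.efficacy:.0%}"
            row[f"treatment_mean_{tag}"] = round(res.treatment_mean_change, 2)
            row[f"d_{tag}"] = round(res.cohens_d, 2)
            row[f"n_total_{tag}"] = res.n_total
        rows.append(row)
    return pd.DataFrame(rows)
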