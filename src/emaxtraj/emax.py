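"""Sigmoid Emax modeling of age-banded change scores.

The model treats age as the "dose" and the mean proportional change in a
cognitive score as the "effect":

    E(a) = E0 + Emax * a^h / (ET50^h + a^h)

``E0`` is the stable pre-decline level of proportional change, ``Emax`` the
asymptotic additional effect of age (negative for decline under the
decline-negative sign convention), ``ET50`` the age of half-maximal effect
and ``h`` the Hill coefficient controlling how abrupt the transition is.

The age at which p% of the maximum effect is reached (EC_p) has the closed
form ``ET50 * (p / (100 - p))^(1/h)``; EC_1 is the earliest detectable age
of decline and is the quantity of primary scientific interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = [
    "EmaxParams",
    "FitConfig",
    "EmaxFit",
    "ECpResult",
    "emax_curve",
    "fit_emax",
    "ecp",
    "fit_report",
]

NON_CONVERGED_MARK = "–"  # en dash, as rendered in the tabular reports


@dataclass(frozen=True)
class EmaxParams:
    """Parameters of the sigmoid Emax curve."""

    E0: float
    Emax: float
    ET50: float
    h: float

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if not self.ET50 > 0:
            raise ValueError(f"ET50 must be > 0, got {self.ET50}")


@dataclass(frozen=True)
class FitConfig:
    """Controls the bounded multi-start least-squares fit.

    ``band_coordinate`` selects the age assigned to a 5-year band: the
    window midpoint (``band_start + 2``, default) or the band start.
    ``weight_by_n`` applies inverse-variance weights proportional to each
    band's observation count: band means are averages, so their sampling
    variance scales as 1/n, and the oldest bands (a handful of members)
    would otherwise dominate the fit noise.
    """

    start_et50: Sequence[float] = (55.0, 65.0, 75.0, 85.0, 95.0)
    start_h: Sequence[float] = (1.0, 4.0, 8.0, 16.0, 32.0)
    weight_by_n: bool = True
    et50_bounds: tuple[float, float] = (20.0, 130.0)
    h_bounds: tuple[float, float] = (0.1, 50.0)
    emax_abs_bound: float = 2.0
    tolerance: float = 1e-10
    band_coordinate: str = "midpoint"  # or "start"

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if not (self.start_et50 and self.start_h):
            raise ValueError("start grid must be nonempty")
        if self.band_coordinate not in ("midpoint", "start"):
            raise ValueError(f"unknown band_coordinate {self.band_coordinate!r}")


@dataclass
class EmaxFit:
    """Outcome of one fit; ``params`` is present only when converged.

    Non-convergence is a first-class result (reported as an en dash in
    tables), never an exception: poorly identified series legitimately
    fail, e.g. when the Hill slope runs to its bound on step-like data.
    """

    params: EmaxParams | None
    converged: bool
    rss: float
    n_points: int
    fit_diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ECpResult:
    """Age (and its 5-year band label) at p% of the maximum age effect."""

    p: float
    age_years: float
    band_label: tuple[int, int]
    extrapolated: bool


def emax_curve(params: EmaxParams, age) -> np.ndarray | float:
    """Expected mean proportional change at ``age`` (scalar or array).

    Monotone from E0 (age -> 0) to E0 + Emax (age -> inf).
    """
    a = np.asarray(age, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age must be > 0")
    r = np.power(a / params.ET50, params.h)
    out = params.E0 + params.Emax * r / (1.0 + r)
    return float(out) if np.isscalar(age) else out


def _band_ages(bands, config: FitConfig) -> np.ndarray:
    offset = 0.0
    if config.band_coordinate == "midpoint":
        # midpoint of the integer label (start)-(start+4)
        offset = (bands[0].band_end - bands[0].band_start) / 2.0 if bands else 2.0
    return np.array([b.band_start + offset for b in bands], dtype=float)


def fit_emax(bands, config: FitConfig | None = None) -> EmaxFit:
    """Least-squares fit of the sigmoid Emax curve to a band series.

    Only ``included`` bands enter the fit. A multi-start grid over
    (ET50, h) guards against the local minima typical of Hill models;
    the best start by residual sum of squares wins. The fit is declared
    non-converged when the optimizer fails on every start or when the
    best solution pins ET50, h or Emax to a bound (an unidentified or
    degenerate series).
    """
    if config is None:
        config = FitConfig()
    used = sorted((b for b in bands if b.included), key=lambda b: b.band_start)
    if len(used) < 4:
        raise InsufficientDataError(
            f"need >= 4 included bands to fit 4 parameters, got {len(used)}"
        )
    x = _band_ages(used, config)
    y = np.array([b.mean_prop_change for b in used], dtype=float)
    if config.weight_by_n:
        w = np.sqrt(np.array([max(b.n_obs, 1) for b in used], dtype=float))
        w /= w.mean()
    else:
        w = np.ones_like(y)

    span = max(float(np.ptp(y)), 0.1)
    lo = np.array([y.min() - span, -config.emax_abs_bound,
                   config.et50_bounds[0], config.h_bounds[0]])
    hi = np.array([y.max() + span, config.emax_abs_bound,
                   config.et50_bounds[1], config.h_bounds[1]])

    def residual(theta):
        e0, emax, et50, h = theta
        r = np.power(x / et50, h)
        return w * (e0 + emax * r / (1.0 + r) - y)

    e0_start = float(y[0])
    delta = float(y[-1] - y[0])
    emax_start = delta if abs(delta) > 1e-6 else -0.05

    best = None
    best_start = None
    n_ok = 0
    for et50_0 in config.start_et50:
        for h_0 in config.start_h:
            x0 = np.clip(
                np.array([e0_start, emax_start, et50_0, h_0]), lo + 1e-9, hi - 1e-9
            )
            try:
                res = least_squares(
                    residual, x0, bounds=(lo, hi), method="trf",
                    ftol=config.tolerance, xtol=1e-12, gtol=1e-12, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - optimizer robustness guard
                continue
            if not res.success or not np.all(np.isfinite(res.x)):
                continue
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
                best_start = (et50_0, h_0)

    diagnostics: dict = {"n_starts": len(config.start_et50) * len(config.start_h),
                         "n_successful_starts": n_ok}
    if best is None:
        return EmaxFit(None, False, math.inf, len(used), diagnostics)

    e0, emax, et50, h = (float(v) for v in best.x)
    diagnostics.update(best_start=best_start, iterations=int(best.nfev),
                       best_params={"E0": e0, "Emax": emax, "ET50": et50, "h": h})
    rss = float(2.0 * best.cost)

    def pinned(value, bound_lo, bound_hi):
        tol = 1e-6 * (bound_hi - bound_lo)
        return value - bound_lo < tol or bound_hi - value < tol

    hit_bound = (
        pinned(et50, *config.et50_bounds)
        or pinned(h, *config.h_bounds)
        or pinned(emax, -config.emax_abs_bound, config.emax_abs_bound)
    )
    if hit_bound:
        diagnostics["reason"] = "parameter pinned to bound"
        return EmaxFit(None, False, rss, len(used), diagnostics)
    return EmaxFit(EmaxParams(e0, emax, et50, h), True, rss, len(used), diagnostics)


def ecp(
    params: EmaxParams,
    p: float,
    band_width: int = 5,
    observed_age_range: tuple[float, float] | None = None,
) -> ECpResult:
    """Age at which p% of the maximum age effect is attained.

    Closed-form inversion of the Hill sigmoid:
    ``age = ET50 * (p / (100 - p))**(1 / h)``. The band label is
    ``(floor(age), floor(age) + band_width - 1)``; ``extrapolated`` is set
    when the age lies outside ``observed_age_range``.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must lie in (0, 100), got {p}")
    age = params.ET50 * (p / (100.0 - p)) ** (1.0 / params.h)
    start = math.floor(age)
    extrapolated = False
    if observed_age_range is not None:
        extrapolated = not (observed_age_range[0] <= age <= observed_age_range[1])
    return ECpResult(p, age, (start, start + band_width - 1), extrapolated)


def fit_report(
    fits: Mapping[tuple[str, str], EmaxFit],
    ps: Sequence[float] = (1.0, 5.0, 10.0),
    observed_age_range: tuple[float, float] | None = None,
):
    """Table of EC_p band labels per (group, test).

    Non-converged fits render as an en dash in every EC column, matching
    the tabular convention for models that failed to converge.
    """
    import pandas as pd

    rows = []
    for (group, test), fit in fits.items():
        row: dict = {"group": group, "test": test}
        for p in ps:
            col = f"EC_{p:g}"
            if fit.converged and fit.params is not None:
                res = ecp(fit.params, p, observed_age_range=observed_age_range)
                row[col] = f"{res.band_label[0]}–{res.band_label[1]}"
            else:
                row[col] = NON_CONVERGED_MARK
        rows.append(row)
    cols = ["group", "test"] + [f"EC_{p:g}" for p in ps]
    return pd.DataFrame(rows, columns=cols)
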