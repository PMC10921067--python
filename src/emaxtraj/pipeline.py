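"""End-to-end orchestration: cohort -> changes -> bands -> fits -> power.

One :class:`RunConfig` drives the whole analysis reproducibly: the same
configuration and seed produce identical outputs. Per (group, test) the
run writes the change-score table, the band series, fit parameters, the
EC_p band-label report, the power report for the configured scenarios,
a curve plot, and a machine-readable manifest reconciling every
exclusion against the input size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .bands import BandingRules, summarize_moving_bands
from .emax import EmaxFit, FitConfig, NON_CONVERGED_MARK, ecp, fit_emax, fit_report
from .errors import EmptySeriesError, InsufficientDataError, SpecValidationError
from .io import read_cohort, write_bands, write_changes, write_cohort
from .power import PowerScenario, band_change_stats, power_report
from .prep import EligibilityRules, compute_changes, exclusion_counts, filter_eligible
from .synthetic import CohortSpec, TestSpec, default_tests, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_cohort"]


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of cohort_spec / input_path."""

    output_dir: str | Path
    cohort_spec: CohortSpec | None = None
    input_path: str | Path | None = None
    tests: Sequence[TestSpec] = field(default_factory=default_tests)
    eligibility: EligibilityRules = field(default_factory=EligibilityRules)
    banding: BandingRules = field(default_factory=BandingRules)
    fit: FitConfig = field(default_factory=FitConfig)
    scenarios: Sequence[PowerScenario] = field(
        default_factory=lambda: (PowerScenario(0.35), PowerScenario(0.75))
    )
    power_bands: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    power_group: str = "AD"
    exclude_ids: Sequence[str] = ()
    ec_ps: Sequence[float] = (1.0, 5.0, 10.0)
    round_d: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_spec = self.cohort_spec is not None
        have_path = self.input_path is not None
        if have_spec == have_path:
            raise SpecValidationError(
                "exactly one of cohort_spec / input_path must be provided"
            )


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31 (stable across processes)."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (1 << 31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_spec is not None:
        spec = dataclasses.replace(
            config.cohort_spec, seed=_stage_seed(config.seed, "simulate")
        )
        records = generate_cohort(spec)
        write_cohort(records, out / "cohort.csv")
        tests = list(spec.tests)
    else:
        records = read_cohort(config.input_path)
        tests = list(config.tests)

    eligible = filter_eligible(records, config.eligibility)
    excl = exclusion_counts(records, config.eligibility)

    fits: dict[tuple[str, str], EmaxFit] = {}
    fit_params_json: dict[str, dict | None] = {}
    band_ranges: dict[tuple[str, str], tuple[float, float]] = {}
    groups = sorted({r.group for r in eligible})
    for test in tests:
        for group in groups:
            tag = f"{group}_{test.test_name}"
            members = [r for r in eligible if r.group == group]
            changes = compute_changes(members, test)
            write_changes(changes, out / f"changes_{tag}.csv")
            try:
                series = summarize_moving_bands(
                    changes, config.banding, exclude_ids=config.exclude_ids
                )
            except EmptySeriesError:
                logger.warning("bands[%s]: empty series, skipping fit", tag)
                fits[(group, test.test_name)] = EmaxFit(
                    None, False, float("inf"), 0, {"reason": "empty band series"}
                )
                fit_params_json[tag] = None
                continue
            write_bands(series, out / f"bands_{tag}.csv")
            ages = [c.baseline_age for c in changes
                    if c.baseline_age >= config.banding.first_band_start]
            band_ranges[(group, test.test_name)] = (min(ages), max(ages))
            try:
                fit = fit_emax(series, config.fit)
            except InsufficientDataError as exc:
                logger.warning("fit[%s]: %s", tag, exc)
                fit = EmaxFit(None, False, float("inf"), 0, {"reason": str(exc)})
            fits[(group, test.test_name)] = fit
            fit_params_json[tag] = (
                dataclasses.asdict(fit.params) if fit.converged else None
            )
            _plot_fit(series, fit, out / f"fit_{tag}.png",
                      f"{group} / {test.test_name}", config.fit)

    report = fit_report(fits, config.ec_ps)
    report.to_csv(out / "ecp_report.csv", index=False)

    power_rows = {}
    power_changes = {}
    for test in tests:
        band = config.power_bands.get(test.test_name)
        if band is None:
            continue
        members = [r for r in eligible if r.group == config.power_group]
        changes = compute_changes(members, test)
        duration = config.scenarios[0].trial_duration if config.scenarios else 2.0
        try:
            stats = band_change_stats(changes, tuple(band), duration)
        except InsufficientDataError as exc:
            logger.warning("power[%s]: %s", test.test_name, exc)
            continue
        power_rows[(test.test_name, tuple(band))] = stats
        power_changes[test.test_name] = stats
    if power_rows:
        power_report(power_rows, config.scenarios, round_d=config.round_d).to_csv(
            out / "power_report.csv", index=False
        )

    manifest = {
        "package_version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "config": _config_echo(config),
        "exclusions": excl,
        "n_input": len(records),
        "n_eligible": len(eligible),
        "fits": {
            tag: params for tag, params in sorted(fit_params_json.items())
        },
        "ecp_report": _machine_report(fits, config.ec_ps),
        "power_bands_used": {t: list(b) for t, b in config.power_bands.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _machine_report(fits, ps) -> dict:
    """EC_p ages with explicit nulls (the tables use an en dash instead)."""
    out = {}
    for (group, test), fit in fits.items():
        key = f"{group}_{test}"
        if fit.converged and fit.params is not None:
            out[key] = {f"EC_{p:g}": ecp(fit.params, p).age_years for p in ps}
        else:
            out[key] = {f"EC_{p:g}": None for p in ps}
    return out


def _config_echo(config: RunConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)

    return json.loads(json.dumps(dataclasses.asdict(config), default=default))


def _library_versions() -> dict:
    import pandas
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__}


def _plot_fit(series, fit: EmaxFit, path: Path, title: str, config: FitConfig) -> None:
    """Band means with the fitted sigmoid overlaid (skipped when not converged)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .emax import emax_curve

    used = [b for b in series if b.included]
    fig, ax = plt.subplots(figsize=(6, 4))
    offset = (config.band_coordinate == "midpoint") * 2.0
    ax.scatter([b.band_start + offset for b in used],
               [b.mean_prop_change for b in used],
               s=18, color="tab:blue", label="band means")
    if fit.converged and fit.params is not None:
        xs = np.linspace(40, 120, 400)
        ax.plot(xs, emax_curve(fit.params, xs), color="tab:red", label="Emax fit")
        subtitle = (f"ET50={fit.params.ET50:.1f}, h={fit.params.h:.1f}, "
                    f"Emax={fit.params.Emax:.3f}")
    else:
        subtitle = f"not converged ({NON_CONVERGED_MARK})"
    ax.set_xlabel("baseline age (years)")
    ax.set_ylabel("mean proportional change")
    ax.set_title(f"{title}\n{subtitle}", fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
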