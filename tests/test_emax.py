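"""Sigmoid Emax curve, fitting, EC_p inversion and reporting."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emaxtraj import (
    EmaxFit,
    EmaxParams,
    FitConfig,
    ecp,
    emax_curve,
    fit_emax,
    fit_report,
)
from emaxtraj.bands import AgeBandSummary
from emaxtraj.errors import InsufficientDataError


def series_from(starts, values, n_obs=10, included=True):
    return [
        AgeBandSummary(int(s), int(s) + 4, n_obs, float(v), included)
        for s, v in zip(starts, values)
    ]


class TestCurve:
    def test_half_max_identity(self):
        p = EmaxParams(E0=0.1, Emax=-0.6, ET50=75.0, h=3.0)
        assert emax_curve(p, 75.0) == pytest.approx(0.1 - 0.3)

    def test_flat_when_emax_zero(self):
        p = EmaxParams(E0=0.05, Emax=0.0, ET50=75.0, h=3.0)
        for age in (40.0, 75.0, 110.0):
            assert emax_curve(p, age) == 0.05

    def test_half_max_with_numbers(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        assert emax_curve(p, 80.0) == pytest.approx(-0.2)

    def test_monotone_between_asymptotes(self):
        p = EmaxParams(E0=0.02, Emax=-0.5, ET50=80.0, h=6.0)
        ages = np.linspace(1.0, 200.0, 500)
        values = emax_curve(p, ages)
        assert np.all(np.diff(values) <= 0)
        assert values[0] <= p.E0 + 1e-6 and values[-1] >= p.E0 + p.Emax - 1e-6

    def test_domain_errors(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        with pytest.raises(ValueError):
            emax_curve(p, 0.0)
        with pytest.raises(ValueError):
            EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=0.0)
        with pytest.raises(ValueError):
            EmaxParams(E0=0.0, Emax=-0.4, ET50=-5.0, h=2.0)


class TestEcp:
    def test_p50_is_et50_exactly(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=83.7, h=7.3)
        assert ecp(p, 50.0).age_years == 83.7

    def test_known_inversion(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        assert ecp(p, 1.0).age_years == pytest.approx(50.527, abs=1e-3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        et50=st.floats(30.0, 120.0),
        h=st.floats(0.5, 40.0),
    )
    def test_strictly_increasing_in_p(self, et50, h):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=et50, h=h)
        ages = [ecp(p, q).age_years for q in (1.0, 5.0, 10.0, 50.0, 90.0)]
        assert all(a < b for a, b in zip(ages, ages[1:]))

    def test_band_label_floor_rule(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        res = ecp(p, 50.0)
        assert res.band_label == (80, 84)
        res2 = ecp(p, 1.0)  # 50.53 years
        assert res2.band_label == (50, 54)

    def test_extrapolation_flag(self):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        assert ecp(p, 1.0, observed_age_range=(65.0, 90.0)).extrapolated
        assert not ecp(p, 50.0, observed_age_range=(65.0, 90.0)).extrapolated

    @pytest.mark.parametrize("bad_p", [0.0, -1.0, 100.0, 120.0])
    def test_p_domain(self, bad_p):
        p = EmaxParams(E0=0.0, Emax=-0.4, ET50=80.0, h=10.0)
        with pytest.raises(ValueError):
            ecp(p, bad_p)


class TestFit:
    truth = EmaxParams(E0=0.02, Emax=-0.35, ET50=78.0, h=8.0)

    def make_series(self, starts=range(65, 93)):
        values = [emax_curve(self.truth, s + 2.0) for s in starts]
        return series_from(starts, values)

    def test_noise_free_parameter_recovery(self):
        fit = fit_emax(self.make_series())
        assert fit.converged
        for name in ("E0", "Emax", "ET50", "h"):
            est, true = getattr(fit.params, name), getattr(self.truth, name)
            assert abs(est - true) / abs(true) < 1e-3

    def test_fit_invariant_to_order_and_excluded_bands(self):
        series = self.make_series()
        shuffled = series[:]
        random.Random(0).shuffle(shuffled)
        junk = series_from([95, 99], [3.0, -3.0], included=False)
        a = fit_emax(series)
        b = fit_emax(shuffled + junk)
        assert b.converged
        assert a.params.ET50 == pytest.approx(b.params.ET50, rel=1e-9)

    def test_three_bands_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_emax(self.make_series(starts=[65, 70, 75]))

    def test_constant_series_never_crashes(self):
        fit = fit_emax(series_from(range(65, 85), [0.01] * 20))
        if fit.converged:
            assert abs(fit.params.Emax) < 1e-6

    def test_step_series_reports_non_convergence(self):
        """A discontinuous step has no finite Hill slope; the fit pins h
        at its bound and must report converged=False, not raise."""
        starts = list(range(65, 85))
        values = [0.0 if s + 2 < 79 else -0.4 for s in starts]
        fit = fit_emax(series_from(starts, values))
        assert not fit.converged
        assert fit.params is None

    def test_band_coordinate_start_shifts_fit(self):
        series = self.make_series()
        mid = fit_emax(series, FitConfig(band_coordinate="midpoint"))
        start = fit_emax(series, FitConfig(band_coordinate="start"))
        assert start.converged
        # same curve expressed on ages shifted by 2 years
        assert start.params.ET50 == pytest.approx(mid.params.ET50 - 2.0, abs=0.2)


class TestReport:
    def test_non_converged_renders_dash(self):
        fits = {("AD", "tmt_b"): EmaxFit(None, False, math.inf, 0)}
        table = fit_report(fits, (1.0, 5.0, 10.0))
        assert list(table.loc[0, ["EC_1", "EC_5", "EC_10"]]) == ["–", "–", "–"]

    def test_floor_label_rendering(self):
        # EC_1 at 67.3 years must label as 67–71
        h = 10.0
        et50 = 67.3 / (1.0 / 99.0) ** (1.0 / h)
        fit = EmaxFit(EmaxParams(0.0, -0.4, et50, h), True, 0.0, 20)
        table = fit_report({("AD", "mmse"): fit}, (1.0,))
        assert table.loc[0, "EC_1"] == "67–71"

    def test_empty_fits_empty_table(self):
        assert fit_report({}, (1.0,)).empty
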