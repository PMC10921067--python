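"""Static/moving age bands and Tukey-fence outlier exclusion."""

import random

import numpy as np
import pytest

from emaxtraj import BandingRules, summarize_moving_bands
from emaxtraj.bands import assign_static_bands, flag_outliers, outlier_ids
from emaxtraj.errors import EmptySeriesError
from emaxtraj.prep import ChangeRecord


def change(age, value, pid=None):
    return ChangeRecord(
        participant_id=pid or f"p{age}_{value}",
        group="control",
        test_name="mmse",
        baseline_age=float(age),
        followup_years=3.5,
        raw_change=value * 28.0,
        proportional_change=float(value),
    )


class TestStaticBands:
    def test_half_open_boundaries(self):
        bands = assign_static_bands([change(69.9, -0.1), change(70.0, -0.1)])
        assert sorted(bands) == [65, 70]
        assert bands[65][0].baseline_age == 69.9
        assert bands[70][0].baseline_age == 70.0

    def test_counts(self):
        bands = assign_static_bands([change(a, -0.1) for a in (65, 66, 71)])
        assert {s: len(m) for s, m in bands.items()} == {65: 2, 70: 1}

    def test_underage_records_dropped(self):
        bands = assign_static_bands([change(60.0, -0.1), change(66.0, -0.1)])
        assert sum(len(m) for m in bands.values()) == 1


class TestOutlierFences:
    def test_single_gross_outlier_flagged(self):
        members = [change(66 + i, -0.1, pid=str(i)) for i in range(4)]
        members.append(change(67, -5.0, pid="out"))
        flags = dict((c.participant_id, f) for c, f in flag_outliers(members))
        assert flags == {"0": False, "1": False, "2": False, "3": False, "out": True}

    def test_identical_values_never_flagged(self):
        members = [change(66, -0.2, pid=str(i)) for i in range(6)]
        assert not any(f for _, f in flag_outliers(members))

    def test_single_member_not_flagged(self):
        assert flag_outliers([change(66, -3.0)]) [0][1] is False

    def test_flags_invariant_to_member_order(self):
        rng = random.Random(0)
        members = [change(65 + rng.random() * 5, rng.gauss(-0.1, 0.05), pid=str(i))
                   for i in range(30)]
        members[7] = change(66, -4.0, pid="7")
        base = dict((c.participant_id, f) for c, f in flag_outliers(members))
        shuffled = members[:]
        rng.shuffle(shuffled)
        assert dict((c.participant_id, f) for c, f in flag_outliers(shuffled)) == base


class TestMovingBands:
    def test_window_bookkeeping(self):
        changes = [change(a, -0.1) for a in (65, 66, 67, 68, 69)]
        series = summarize_moving_bands(changes, BandingRules(min_obs=4))
        by_start = {b.band_start: b for b in series}
        assert by_start[65].n_obs == 5 and by_start[65].included
        assert by_start[66].n_obs == 4 and by_start[66].included
        assert series[-1].band_start == 69  # last window overlapping any data

    def test_band_below_min_obs_marked_excluded(self):
        changes = [change(a, -0.1) for a in (65.2, 66.1, 67.4)]
        series = summarize_moving_bands(changes)
        assert all(b.n_obs == 3 and not b.included for b in series[:1])

    def test_band_labels_span_width(self):
        changes = [change(a, -0.1) for a in (65, 72, 80)]
        for b in summarize_moving_bands(changes):
            assert b.band_end - b.band_start == 4

    def test_outlier_excluded_from_every_containing_window(self):
        changes = [change(65 + i * 0.5, -0.1, pid=str(i)) for i in range(10)]
        changes.append(change(66.0, -9.0, pid="out"))
        series = summarize_moving_bands(changes, BandingRules(min_obs=1))
        assert "out" in outlier_ids(changes)
        for b in series:
            if b.band_start <= 66.0 < b.band_start + 5:
                assert b.n_obs == sum(
                    1 for c in changes[:-1]
                    if b.band_start <= c.baseline_age < b.band_start + 5
                )

    def test_conservation_of_mass(self):
        """With min_obs=1 and no outliers, static-band means weighted by
        their counts recover the overall mean."""
        rng = random.Random(1)
        changes = [change(65 + rng.random() * 20, rng.uniform(-0.2, 0.0), pid=str(i))
                   for i in range(80)]
        statics = assign_static_bands(changes)
        total = sum(
            len(m) * np.mean([c.proportional_change for c in m])
            for m in statics.values()
        )
        assert total / len(changes) == pytest.approx(
            np.mean([c.proportional_change for c in changes])
        )

    def test_user_exclusion_list(self):
        changes = [change(66 + i * 0.1, -0.1, pid=str(i)) for i in range(6)]
        series = summarize_moving_bands(changes, exclude_ids=["0", "1"])
        assert max(b.n_obs for b in series) == 4

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptySeriesError):
            summarize_moving_bands([change(50.0, -0.1)])  # below first band
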