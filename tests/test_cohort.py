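import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irepulse as ip


class TestVolumeFormulas:
    def test_screening_example(self):
        assert ip.volume_screening(10.0, 20.0) == pytest.approx(1000.0)

    @given(d=st.floats(0.5, 30))
    @settings(max_examples=30, deadline=None)
    def test_screening_cube_identity(self, d):
        assert ip.volume_screening(d, d) == pytest.approx(d**3 / 2)

    def test_screening_homogeneity(self):
        base = ip.volume_screening(4.0, 9.0)
        assert ip.volume_screening(8.0, 9.0) == pytest.approx(4 * base)
        assert ip.volume_screening(4.0, 18.0) == pytest.approx(2 * base)

    def test_followup_example(self):
        # pi/6 * 1.69 * (10*10)^(3/2) = 884.88193...
        assert ip.volume_followup(10.0, 10.0) == pytest.approx(884.8819307611, rel=1e-9)

    def test_followup_f_cancellation(self):
        assert ip.volume_followup(1.0, 1.0, f=6.0 / math.pi) == pytest.approx(1.0)

    @given(l=st.floats(1, 30), w=st.floats(1, 30), a=st.floats(0.5, 4))
    @settings(max_examples=30, deadline=None)
    def test_followup_scaling(self, l, w, a):
        # V scales as (l*w)^(3/2)
        v = ip.volume_followup(l, w)
        assert ip.volume_followup(a * l, a * w) == pytest.approx(a**3 * v, rel=1e-9)

    @given(
        vol=st.floats(5.0, 3000.0),
        rho=st.floats(0.31, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_inversion_round_trip(self, vol, rho):
        length, width = ip.invert_volume_followup(vol, rho)
        assert width <= length + 1e-12
        assert ip.volume_followup(length, width) == pytest.approx(vol, rel=1e-9)

    def test_monotone_in_each_dimension(self):
        assert ip.volume_followup(11.0, 8.0) > ip.volume_followup(10.0, 8.0)
        assert ip.volume_followup(10.0, 9.0) > ip.volume_followup(10.0, 8.0)
        assert ip.volume_screening(5.0, 10.0) < ip.volume_screening(6.0, 10.0)

    def test_nonpositive_inputs_rejected(self):
        for fn in (ip.volume_screening, ip.volume_followup):
            with pytest.raises(ValueError):
                fn(0.0, 5.0)
        with pytest.raises(ValueError):
            ip.invert_volume_followup(100.0, 1.2)  # width > length


class TestEnrollment:
    def test_boundary_value_enrolled(self):
        enrolled, excluded = ip.enrollment_filter([999.0, 1000.0, 1000.1])
        assert list(enrolled) == [0, 1]
        assert list(excluded) == [2]

    def test_all_small_none_excluded(self):
        enrolled, excluded = ip.enrollment_filter(np.full(10, 500.0))
        assert len(enrolled) == 10 and len(excluded) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ip.enrollment_filter([])


class TestRandomization:
    GROUPS = ["control", "500V", "700V", "900V"]

    def test_balanced_and_deterministic(self):
        ids = [f"M{i}" for i in range(24)]
        a1 = ip.randomize_groups(ids, self.GROUPS, seed=7)
        a2 = ip.randomize_groups(ids, self.GROUPS, seed=7)
        assert a1 == a2
        counts = pd.Series(list(a1.values())).value_counts()
        assert all(counts[g] == 6 for g in self.GROUPS)

    def test_seeds_differ(self):
        ids = list(range(24))
        base = ip.randomize_groups(ids, self.GROUPS, seed=0)
        differing = sum(
            ip.randomize_groups(ids, self.GROUPS, seed=s) != base
            for s in range(1, 101)
        )
        assert differing >= 99

    def test_imbalance_rejected(self):
        with pytest.raises(ValueError):
            ip.randomize_groups(list(range(23)), self.GROUPS, seed=0)


class TestFoldChange:
    def _traj(self, values):
        return pd.Series(values, index=[0, 7])

    def test_equal_growth_is_one(self):
        t = self._traj([100.0, 200.0])
        c = self._traj([50.0, 100.0])
        assert ip.relative_fold_change(t, c, 0, 7)["value"] == pytest.approx(1.0)

    def test_halving_against_flat_control(self):
        t = self._traj([100.0, 50.0])
        c = self._traj([80.0, 80.0])
        assert ip.relative_fold_change(t, c, 0, 7)["value"] == pytest.approx(0.5)

    def test_treated_only_definition(self):
        t = self._traj([100.0, 50.0])
        c = self._traj([80.0, 160.0])
        r = ip.relative_fold_change(t, c, 0, 7, definition="treated-only")
        assert r["value"] == pytest.approx(0.5)
        assert r["definition"] == "treated-only"

    def test_zero_denominator_raises(self):
        t = self._traj([0.0, 50.0])
        c = self._traj([80.0, 160.0])
        with pytest.raises(ZeroDivisionError):
            ip.relative_fold_change(t, c, 0, 7)

    def test_missing_day_raises(self):
        t = self._traj([100.0, 50.0])
        c = self._traj([80.0, 160.0])
        with pytest.raises(KeyError):
            ip.relative_fold_change(t, c, 0, 14)

    def test_recovers_programmed_relative_change(self):
        """The estimator recovers the generator's programmed fold change."""
        target = 0.17  # default 900 V profile multiplier at the final day
        vals = []
        for seed in range(40):
            table = ip.simulate_cohort(ip.SynthConfig(seed=seed))
            res = ip.TumorResponseModel(table).fit()
            vals.append(res.fold_changes["900V"]["value"])
        assert np.mean(vals) == pytest.approx(target, abs=0.03)


class TestCohortTable:
    def test_swap_normalizes_calipers(self):
        df = pd.DataFrame({
            "animal_id": ["a"], "group": ["control"], "day": [0],
            "length_mm": [5.0], "width_mm": [8.0],
            "body_weight_g": [20.0], "tumor_weight_g": [np.nan],
        })
        table = ip.CohortTable(df)
        row = table.measurements.iloc[0]
        assert row["length_mm"] == 8.0 and row["width_mm"] == 5.0

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            ip.CohortTable(pd.DataFrame({"animal_id": [1]}))

    def test_csv_round_trip(self, tmp_path):
        table = ip.simulate_cohort(ip.SynthConfig(seed=3))
        p = tmp_path / "cohort.csv"
        c = tmp_path / "cond.csv"
        table.to_csv(p, conductivity_path=c)
        back = ip.CohortTable.from_csv(p, c)
        pd.testing.assert_frame_equal(
            back.measurements, table.measurements, check_exact=False, rtol=1e-12
        )
        assert back.conductivity is not None

    def test_volumes_column(self):
        table = ip.simulate_cohort(ip.SynthConfig(seed=1))
        df = table.volumes()
        manual = ip.volume_followup(
            df["length_mm"].to_numpy(), df["width_mm"].to_numpy()
        )
        assert np.allclose(df["volume_mm3"], manual)


@pytest.fixture(scope="module")
def results():
    table = ip.simulate_cohort(ip.SynthConfig(seed=20))
    return ip.TumorResponseModel(table).fit()


class TestTumorResponseModel:
    def test_missing_control_group_rejected(self):
        table = ip.simulate_cohort(ip.SynthConfig(seed=20))
        with pytest.raises(ValueError):
            ip.TumorResponseModel(table, control_group="sham")

    def test_trajectory_table_shape(self, results):
        assert set(results.trajectories.index) == {"control", "500V", "700V", "900V"}
        assert list(results.trajectories.columns) == [0, 1, 3, 7, 12, 14, 21, 28]

    def test_reports_all_tests(self, results):
        assert results.weight_anova is not None
        assert len(results.weight_tukey) == 6
        assert set(results.conductivity_tests) == {"control", "500V", "700V", "900V"}

    def test_summary_mentions_key_sections(self, results):
        text = results.summary()
        for token in ("trajectories", "ANOVA", "Tukey", "paired t", "Fold change"):
            assert token in text

    def test_plot_trajectories_returns_axes(self, results):
        import matplotlib

        matplotlib.use("Agg")
        ax = results.plot_trajectories()
        assert len(ax.lines) == 4
        assert ax.get_yscale() == "log"

    def test_determinism_byte_identical_report(self):
        t1 = ip.simulate_cohort(ip.SynthConfig(seed=77))
        t2 = ip.simulate_cohort(ip.SynthConfig(seed=77))
        r1 = ip.TumorResponseModel(t1).fit()
        r2 = ip.TumorResponseModel(t2).fit()
        assert r1.to_json() == r2.to_json()
        assert r1.summary() == r2.summary()
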