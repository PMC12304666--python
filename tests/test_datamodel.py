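"""Data model validation and CSV round-trip fidelity."""

import numpy as np
import pandas as pd
import pytest

import funcresp as fr
from funcresp import (
    DamageSeries,
    ExperimentDesign,
    PredationTrial,
    SchemaError,
    ValidationError,
)


class TestPredationTrial:
    def test_direct_parse_equivalent(self, tmp_path):
        p = tmp_path / "trials.csv"
        p.write_text("predator_instar,treatment,n0,na,exposure_h,replicate_id\n1,control,2,1,24,1\n")
        (t,) = fr.read_trials(p)
        assert t == PredationTrial(predator_instar=1, treatment="control", n0=2, na=1, exposure_h=24.0, replicate_id=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n0=4, na=5),  # more consumed than offered
            dict(n0=0, na=0),  # nothing offered
            dict(n0=2, na=-1),
            dict(n0=2, na=1, exposure_h=0.0),
            dict(n0=2, na=1, predator_instar=4),
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(predator_instar=1, treatment="control", n0=2, na=1)
        with pytest.raises(ValidationError):
            PredationTrial(**{**base, **kwargs})

    def test_na_gt_n0_cites_row(self, tmp_path):
        p = tmp_path / "trials.csv"
        p.write_text("predator_instar,treatment,n0,na\n1,control,4,2\n1,control,4,5\n")
        with pytest.raises(ValidationError, match="row 2"):
            fr.read_trials(p)

    def test_fractional_count_is_error_not_rounding(self, tmp_path):
        p = tmp_path / "trials.csv"
        p.write_text("predator_instar,treatment,n0,na\n1,control,4,2.5\n")
        with pytest.raises(ValidationError, match="integer"):
            fr.read_trials(p)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "trials.csv"
        p.write_text("predator_instar,treatment,n0\n1,control,4\n")
        with pytest.raises(SchemaError, match="na"):
            fr.read_trials(p)

    def test_treatment_labels_normalized_lowercase(self):
        t = PredationTrial(predator_instar=1, treatment="  Cry3Aa ", n0=2, na=0)
        assert t.treatment == "cry3aa"


class TestExperimentDesign:
    @pytest.mark.parametrize("densities", [(4, 2, 8), (2, 2, 4), (0, 2)])
    def test_densities_must_strictly_increase(self, densities):
        with pytest.raises(ValidationError):
            ExperimentDesign(densities=densities)

    def test_trial_count(self):
        assert ExperimentDesign(densities=(2, 4, 8), replicates=15).n_trials == 45


def test_trials_round_trip_full_preset_suite(tmp_path):
    """Write->read on the 420 simulated study trials reproduces every field."""
    trials = []
    for i, params in enumerate(fr.FR_PRESETS.values()):
        trials.extend(fr.simulate_trials(params, seed=100 + i))
    assert len(trials) == 420  # (3 + 4 + 7 densities) x 15 reps x 2 treatments
    p = tmp_path / "trials.csv"
    fr.write_trials(trials, p)
    back = fr.read_trials(p)
    assert back == trials


def test_damage_round_trip_and_grouping(tmp_path):
    series = []
    for name, params in fr.DAMAGE_PRESETS.items():
        series.extend(fr.simulate_damage(params, replicates=15, seed=5))
    p = tmp_path / "damage.csv"
    fr.write_damage_series(series, p)
    assert len(pd.read_csv(p)) == 4 * 15 * 8  # 480 day-records
    back = fr.read_damage_series(p)
    assert len(back) == 60  # grouped into 60 per-replicate series
    assert sorted((s.treatment, s.replicate) for s in back) == sorted((s.treatment, s.replicate) for s in series)


class TestDamageSeries:
    def test_survivor_increase_rejected(self):
        with pytest.raises(ValidationError, match="increase"):
            DamageSeries("t1", 1, days=(0, 1, 2), survivors=(5, 3, 4), defoliation_pct=(0, 1, 2))

    def test_day_gap_rejected(self):
        with pytest.raises(ValidationError, match="gap"):
            DamageSeries("t1", 1, days=(0, 1, 3), survivors=(5, 5, 5), defoliation_pct=(0, 1, 2))

    def test_survivor_increase_in_csv_rejected(self, tmp_path):
        p = tmp_path / "damage.csv"
        p.write_text(
            "treatment,replicate,day,survivors,defoliation_pct\n"
            "t1,1,3,5,10\nt1,1,4,7,11\n"
        )
        with pytest.raises(ValidationError):
            fr.read_damage_series(p)

    def test_empty_file_with_header(self, tmp_path, caplog):
        p = tmp_path / "damage.csv"
        p.write_text("treatment,replicate,day,survivors,defoliation_pct\n")
        with caplog.at_level("WARNING", logger="funcresp"):
            assert fr.read_damage_series(p) == []
        assert any("no damage rows" in r.message for r in caplog.records)

    def test_decreasing_defoliation_warns_or_errors(self, tmp_path, caplog):
        p = tmp_path / "damage.csv"
        p.write_text(
            "treatment,replicate,day,survivors,defoliation_pct\n"
            "t1,1,0,5,10\nt1,1,1,5,8\n"
        )
        with caplog.at_level("WARNING", logger="funcresp"):
            fr.read_damage_series(p)
        assert any("defoliation decreases" in r.message for r in caplog.records)
        with pytest.raises(ValidationError):
            fr.read_damage_series(p, strict_defoliation=True)


class TestWriteResults:
    def _fit(self, instar, treatment, th, th_cl, a=0.1, a_cl=(0.05, 0.2)):
        tth, tth_cl = fr.max_attack(th, th_cl, 24.0)
        return fr.RogersFit(
            instar=instar, treatment=treatment, a_hat=a, th_hat=th, a_cl=a_cl, th_cl=th_cl,
            tth_hat=tth, tth_cl=tth_cl, exposure_h=24.0, n_trials=45, sse=1.0, converged=True,
        )

    def test_disjoint_th_cls_get_distinct_letters(self, tmp_path):
        fits = [
            self._fit(1, "control", 17.84, (13.02, 22.65)),
            self._fit(1, "cry3aa", 8.23, (7.48, 8.99)),
        ]
        fr.write_results([], fits, tmp_path)
        df = pd.read_csv(tmp_path / "table2.csv")
        assert set(df.group_letter) == {"a", "b"}
        assert list(df.columns[:11]) == [
            "instar", "treatment", "a_hat", "a_lo", "a_hi",
            "th_hat", "th_lo", "th_hi", "tth_hat", "tth_lo", "tth_hi",
        ]

    def test_single_fit_letter_a(self, tmp_path):
        fr.write_results([], [self._fit(1, "control", 10.0, (8.0, 12.0))], tmp_path)
        df = pd.read_csv(tmp_path / "table2.csv")
        assert list(df.group_letter) == ["a"]

    def test_empty_fit_lists_write_headers_only(self, tmp_path):
        fr.write_results([], [], tmp_path)
        assert len(pd.read_csv(tmp_path / "table1.csv")) == 0
        assert len(pd.read_csv(tmp_path / "table2.csv")) == 0
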