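import numpy as np
import pandas as pd
import pytest

from phytomer import reconstruction as rc
from phytomer import synthetic_data as sd
from phytomer.growth_model import SigmoidCurve, invert_sigmoid


def _obs(rows):
    df = pd.DataFrame(
        rows,
        columns=["tiller_id", "day", "rank", "distance", "reference_ligule_rank"],
    )
    df["treatment"] = "N1V1"
    return df


class TestEstimateEmergence:
    def test_lag_is_distance_over_rate(self):
        obs = _obs(
            [("t", 23, 9, 0.0, 7)]  # pre-existing rank so day 24 is not the start
            + [("t", d, 10, x, 8) for d, x in [(24, 6.0), (25, 18.0), (26, 30.0)]]
        )
        ev = rc.estimate_emergence(obs)
        row = ev[ev["rank"] == 10].iloc[0]
        assert row["rate"] == 12.0
        assert row["lag"] == pytest.approx(0.5)
        assert row["emergence_day"] == pytest.approx(23.5)

    def test_zero_first_distance_means_zero_lag(self):
        obs = _obs(
            [("t", 23, 9, 0.0, 7)]
            + [("t", d, 10, x, 8) for d, x in [(25, 0.0), (26, 12.0), (27, 24.0)]]
        )
        row = rc.estimate_emergence(obs).set_index("rank").loc[10]
        assert row["lag"] == 0.0 and row["emergence_day"] == 25.0

    def test_rank_present_at_window_start_is_censored(self):
        obs = _obs([("t", d, 10, x, 8) for d, x in [(24, 6.0), (25, 18.0), (26, 30.0)]])
        assert rc.estimate_emergence(obs).empty

    def test_non_positive_rate_flagged(self):
        obs = _obs(
            [("t", 23, 9, 0.0, 7)]
            + [("t", d, 10, x, 8) for d, x in [(25, 6.0), (26, 6.0), (27, 6.0), (28, 6.0), (29, 6.0)]]
        )
        ev = rc.estimate_emergence(obs)
        assert ev[ev["rank"] == 10]["flagged"].iloc[0]

    def test_zero_noise_emergence_within_half_day_of_truth(self, noiseless_experiment):
        obs, _, truth = noiseless_experiment
        ev = rc.estimate_emergence(obs)
        ev = ev[~ev["flagged"]]
        tru = truth.set_index(["tiller_id", "rank"])["true_emergence_day"]
        errs = [
            row["emergence_day"] - tru.loc[(row["tiller_id"], row["rank"])]
            for _, row in ev.iterrows()
        ]
        assert np.max(np.abs(errs)) < 0.5


class TestPhyllochron:
    def test_mean_of_consecutive_differences(self):
        ev = pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "x",
                "rank": [10, 11, 12],
                "emergence_day": [24.0, 26.3, 28.6],
                "flagged": False,
            }
        )
        out = rc.compute_phyllochron(ev)
        assert out["phyllochron"].iloc[0] == pytest.approx(2.3)

    def test_single_event_is_an_error(self):
        ev = pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "x",
                "rank": [10],
                "emergence_day": [24.0],
                "flagged": False,
            }
        )
        with pytest.raises(ValueError):
            rc.compute_phyllochron(ev)

    def test_recovers_treatment_phyllochrons(self, experiment, default_config):
        obs, _, _ = experiment
        ev = rc.estimate_emergence(obs)
        phy = rc.compute_phyllochron(ev, strict=False)
        phy["treatment"] = phy["tiller_id"].str[:4]
        means = phy.groupby("treatment")["phyllochron"].mean()
        for spec in default_config.treatments:
            se = phy.loc[phy.treatment == spec.name, "phyllochron"].sem()
            assert abs(means[spec.name] - spec.phyllochron) < max(3 * se, 0.1)


class TestFullExpansion:
    def test_flat_tail_detected_at_first_flat_day(self):
        obs = _obs(
            [("t", d, 12, x, 10) for d, x in
             [(24, 80.0), (25, 88.0), (26, 92.0), (27, 92.0), (28, 92.0)]]
        )
        out = rc.detect_full_expansion(obs)
        assert out["mature"].iloc[0]
        assert out["cessation_day"].iloc[0] == 26.0

    def test_monotone_rising_series_is_immature(self):
        obs = _obs([("t", 24 + i, 12, 10.0 * i, 10) for i in range(6)])
        out = rc.detect_full_expansion(obs)
        assert not out["mature"].iloc[0]

    def test_detected_cessation_within_one_day_of_truth(self, noiseless_experiment):
        obs, _, truth = noiseless_experiment
        cess = rc.detect_full_expansion(obs)
        cess = cess[cess["mature"]]
        tru = truth.set_index(["tiller_id", "rank"])["true_cessation_day"]
        errs = []
        for _, row in cess.iterrows():
            true_day = tru.loc[(row["tiller_id"], row["rank"])]
            if obs["day"].min() + 1 <= true_day <= obs["day"].max():
                errs.append(row["cessation_day"] - true_day)
        assert errs and np.max(np.abs(errs)) <= 1.0


class TestFinalLength:
    def _diss(self, ranks, lengths, maturity="mature"):
        return pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "x",
                "rank": ranks,
                "phytomer_length": lengths,
                "blade": 0.0,
                "sheath": 0.0,
                "internode": 0.0,
                "maturity": maturity,
            }
        )

    def test_constant_line(self):
        d = self._diss([8, 9, 10, 11], [90.0] * 4)
        assert rc.predict_final_length(d, 14) == pytest.approx(90.0)

    def test_collinear_extrapolation(self):
        # 100 mm at rank 8 falling 4 mm per rank -> 76 mm at rank 14
        d = self._diss([8, 9, 10, 11, 12], [100, 96, 92, 88, 84])
        assert rc.predict_final_length(d, 14) == pytest.approx(76.0)

    def test_too_few_mature_ranks(self):
        d = self._diss([8, 9], [100, 96])
        with pytest.raises(ValueError):
            rc.predict_final_length(d, 12)

    def test_one_rank_extrapolation_error_below_5_percent(self, experiment):
        _, diss, truth = experiment
        tru = truth.set_index(["tiller_id", "rank"])["final_length"]
        errs = []
        for tiller_id, g in diss.groupby("tiller_id"):
            mature_max = g.loc[g["maturity"] == "mature", "rank"].max()
            target = mature_max + 1
            if target not in set(g["rank"]):
                continue
            try:
                lp = rc.predict_final_length(g, int(target))
            except ValueError:
                continue
            true_lp = tru.loc[(tiller_id, target)]
            errs.append(abs(lp - true_lp) / true_lp)
        assert len(errs) > 30
        assert np.median(errs) < 0.05


class TestFraction:
    def test_basic_ratio_and_errors(self):
        assert rc.fraction_of_final(46.5, 93.0) == pytest.approx(0.5)
        assert rc.fraction_of_final(93.0, 93.0) == 1.0
        with pytest.raises(ValueError):
            rc.fraction_of_final(10.0, 0.0)

    def test_mature_phytomers_have_fraction_one(self, reconstructed):
        d = reconstructed.dissection
        mature = d[d["maturity"] == "mature"]
        np.testing.assert_allclose(mature["f_L"], 1.0, atol=1e-12)
        imm = d.loc[d["maturity"] == "immature", "f_L"]
        # immature fractions exceed 1 only through final-length prediction
        # noise on nearly-finished phytomers
        assert (imm > 0).all()
        assert np.quantile(imm, 0.95) <= 1.2
        assert imm.max() < 1.5


class TestVisibleTimecourse:
    def test_backward_telescoping(self):
        obs = _obs(
            [("t", 23, 11, 0.0, 9)]
            + [("t", 24 + i, 12, 10.0 * (i + 1), 10) for i in range(8)]
            + [("t", 32, 12, 80.0, 10), ("t", 33, 12, 80.0, 10)]
        )
        ev = rc.estimate_emergence(obs)
        cess = rc.detect_full_expansion(obs)
        diss = pd.DataFrame(
            {
                "tiller_id": ["t"],
                "treatment": ["N1V1"],
                "rank": [12],
                "phytomer_length": [80.0],
                "maturity": ["mature"],
            }
        )
        tc = rc.build_visible_timecourse(obs, diss, ev, cess)
        f = tc.sort_values("day")["f_L"].to_numpy()
        np.testing.assert_allclose(
            f, [0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0], atol=1e-12
        )

    def test_zero_noise_fraction_matches_truth(self, noiseless_experiment):
        obs, diss, truth = noiseless_experiment
        cfg = sd.default_config(seed=0).without_noise()
        ev = rc.estimate_emergence(obs)
        cess = rc.detect_full_expansion(obs)
        tc = rc.build_visible_timecourse(obs, diss, ev, cess)
        assert len(tc) > 100
        curve = cfg.timecourse()
        tru = truth.set_index(["tiller_id", "rank"])
        for _, row in tc.iterrows():
            t = tru.loc[(row["tiller_id"], row["rank"])]
            f_true = min(curve(row["day"] - t["initiation_day"]) / 0.99, 1.0)
            assert abs(row["f_L"] - f_true) < 0.012


class TestInvisibleAges:
    def test_anchor_inversion_and_phyllochron_stepping(self):
        curve = SigmoidCurve(1.0, 1.82, 1.81)
        diss = pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "N1V1",
                "rank": [14, 15],
                "f_L": [0.70, 0.20],
                "maturity": "immature",
                "phytomer_length": [50.0, 15.0],
                "Lp": [71.0, 73.0],
            }
        )
        out = rc.assign_invisible_ages(diss, curve, 2.3)
        ages = out.set_index("rank")["age"]
        assert ages[14] == pytest.approx(invert_sigmoid(curve, 0.7), abs=1e-9)
        assert ages[14] == pytest.approx(3.35, abs=0.01)
        assert ages[15] == pytest.approx(ages[14] - 2.3)

    def test_anchor_at_midpoint_gives_x0(self):
        curve = SigmoidCurve(1.0, 1.82, 1.81)
        diss = pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "x",
                "rank": [14],
                "f_L": [0.5],
                "maturity": "immature",
                "phytomer_length": [40.0],
                "Lp": [80.0],
            }
        )
        out = rc.assign_invisible_ages(diss, curve, 2.3, anchor_window=(0.4, 0.8))
        assert out["age"].iloc[0] == pytest.approx(1.82)

    def test_no_anchor_candidate_skips_tiller(self, caplog):
        curve = SigmoidCurve(1.0, 1.82, 1.81)
        diss = pd.DataFrame(
            {
                "tiller_id": "t",
                "treatment": "x",
                "rank": [14],
                "f_L": [0.3],
                "maturity": "immature",
                "phytomer_length": [20.0],
                "Lp": [66.0],
            }
        )
        out = rc.assign_invisible_ages(diss, curve, 2.3)
        assert out.empty

    def test_assigned_ages_within_one_phyllochron_of_truth(self, reconstructed, experiment):
        _, _, truth = experiment
        tru = truth.set_index(["tiller_id", "rank"])
        init = reconstructed.timecourse.query("phase == 'initial'")
        assert len(init) > 50
        errs = []
        for _, row in init.iterrows():
            t = tru.loc[(row["tiller_id"], row["rank"])]
            errs.append(row["age"] - (37.0 - t["initiation_day"]))
        phy = 2.4
        assert np.quantile(np.abs(errs), 0.9) < phy


class TestCoordinationTables:
    def test_tables_from_pipeline(self, reconstructed):
        within, between = reconstructed.within, reconstructed.between
        # no sheath before half of final length
        early = within[within["f_L"] < 0.45]
        assert len(early) > 10
        assert (early["sheath_fraction"] == 0).all()
        # pairs ordered older -> younger, mature older partner has f = 1
        assert (between["f_older"] >= between["f_younger"] - 0.3).all()
        mature_pairs = between[between["f_older"] > 0.999]
        assert len(mature_pairs) > 0
        # a young successor barely grows before its predecessor reaches ~25 %
        young = between[between["f_older"] < 0.25]
        if len(young):
            assert young["f_younger"].median() < 0.15

    def test_age_consistency_between_phases(self, reconstructed):
        """Visible and invisible ages agree where the point sets overlap."""
        tc = reconstructed.timecourse
        vis = tc[tc["phase"] == "visible"]
        init = tc[tc["phase"] == "initial"]
        overlap = pd.merge(
            vis, init, on=["tiller_id", "rank"], suffixes=("_vis", "_init")
        )
        if len(overlap):
            # compare the visible age interpolated at the dissection day
            last_vis = vis.groupby(["tiller_id", "rank"]).last().reset_index()
            both = pd.merge(last_vis, init, on=["tiller_id", "rank"], suffixes=("_v", "_i"))
            gap = (both["age_i"] - (both["age_v"] + (37 - both["day_v"]))).abs()
            assert gap.median() < 2.4


def test_pipeline_outputs_are_complete(reconstructed):
    r = reconstructed
    assert not r.events.empty and not r.phyllochron.empty
    assert set(r.timecourse["phase"].unique()) == {"visible", "initial"}
    assert r.complete_fit.converged and 0 <= r.complete_fit.r_squared <= 1
    assert set(r.visible_fits) == {"N1V1", "N1V2", "N2V1", "N2V2"}
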