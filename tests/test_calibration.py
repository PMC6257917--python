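"""Observer size calibration and pair sighting efficiency."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sbtindex.calibration import (CalibrationError, fit_pair_efficiency,
                                  fit_size_calibration, adjust_school_sizes,
                                  sighting_biomass)


def paired_school_frame(rng, betas, reference, n_schools=800, cv=0.2):
    """Schools each estimated by the reference and one other observer."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    others = [o for o in betas if o != reference]
    rows = []
    for i in range(n_schools):
        other = others[i % len(others)]
        true = rng.gamma(1.5, 40.0)
        for obs in (reference, other):
            est = true * betas[obs] * np.exp(rng.normal(-sigma ** 2 / 2, sigma))
            rows.append({"sighting_id": f"s{i}", "school_id": f"sch{i}",
                         "observer": obs, "biomass_t": est, "distance_nm": 1.0})
    return pd.DataFrame(rows)


class TestSizeCalibration:
    def test_recovers_known_biases_within_two_se(self):
        rng = np.random.default_rng(21)
        betas = {5: 1.0, 3: 0.81, 11: 1.10, 7: 0.97}
        df = paired_school_frame(rng, betas, reference=5, n_schools=2000)
        calib = fit_size_calibration(df, reference=5)
        for obs, true_beta in betas.items():
            if obs == 5:
                assert calib.beta[5] == 1.0 and calib.se[5] is None
            else:
                assert abs(calib.beta[obs] - true_beta) < 2 * calib.se[obs]

    def test_identical_estimates_give_unit_betas_zero_se(self):
        rows = []
        for i in range(50):
            for obs in (5, 7):
                rows.append({"school_id": f"s{i}", "sighting_id": f"s{i}",
                             "observer": obs, "biomass_t": 10.0 + i})
        calib = fit_size_calibration(pd.DataFrame(rows), reference=5)
        assert calib.beta[7] == pytest.approx(1.0)
        assert calib.se[7] == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_overlap_graph_names_unreachable_observers(self):
        rows = []
        for i in range(20):  # component {5,7} and component {3,11}
            a, b = (5, 7) if i % 2 == 0 else (3, 11)
            for obs in (a, b):
                rows.append({"school_id": f"s{i}", "sighting_id": f"s{i}",
                             "observer": obs, "biomass_t": 20.0})
        with pytest.raises(CalibrationError, match="disconnected"):
            fit_size_calibration(pd.DataFrame(rows), reference=5)

    def test_chained_overlap_is_identifiable(self):
        # 5-7 and 7-3 overlap: 3 reachable from 5 only through 7
        rng = np.random.default_rng(22)
        rows = []
        for i in range(600):
            pair = (5, 7) if i % 2 == 0 else (7, 3)
            true = rng.gamma(1.5, 40.0)
            for obs in pair:
                beta = {5: 1.0, 7: 0.9, 3: 0.8}[obs]
                rows.append({"school_id": f"s{i}", "sighting_id": f"s{i}",
                             "observer": obs,
                             "biomass_t": true * beta * np.exp(rng.normal(0, 0.2))})
        calib = fit_size_calibration(pd.DataFrame(rows), reference=5)
        assert calib.beta[3] == pytest.approx(0.8, abs=0.06)

    def test_ci_coverage_near_nominal(self):
        # 95% intervals for beta should cover the truth at 95% +/- 3 points
        rng = np.random.default_rng(23)
        betas = {5: 1.0, 3: 0.81, 11: 1.10}
        hits = trials = 0
        for _ in range(200):
            df = paired_school_frame(rng, betas, reference=5, n_schools=300)
            calib = fit_size_calibration(df, reference=5)
            for obs in (3, 11):
                trials += 1
                if abs(calib.beta[obs] - betas[obs]) < 1.96 * calib.se[obs]:
                    hits += 1
        assert 0.92 <= hits / trials <= 0.98


class TestAdjustment:
    def test_division_brings_biased_observer_onto_reference_scale(self):
        calib = fit_size_calibration(pd.DataFrame(
            [{"school_id": f"a{i}", "sighting_id": f"a{i}", "observer": o,
              "biomass_t": v} for i in range(30) for o, v in ((5, 100.0), (3, 81.0))]),
            reference=5)
        assert calib.beta[3] == pytest.approx(0.81, rel=1e-9)
        adj = adjust_school_sizes(pd.DataFrame(
            [{"school_id": "x", "sighting_id": "sx", "observer": 3,
              "biomass_t": 81.0}]), calib)
        assert adj["biomass_t"].iloc[0] == pytest.approx(100.0, rel=1e-9)

    def test_school_biomass_is_mean_of_adjusted_estimates(self):
        calib = _unit_calib()
        adj = adjust_school_sizes(pd.DataFrame(
            [{"school_id": "x", "sighting_id": "s", "observer": 5, "biomass_t": 90.0},
             {"school_id": "x", "sighting_id": "s", "observer": 7, "biomass_t": 110.0}]),
            calib)
        assert adj["biomass_t"].iloc[0] == pytest.approx(100.0)

    def test_unit_betas_leave_estimates_unchanged(self):
        calib = _unit_calib()
        df = pd.DataFrame([{"school_id": "x", "sighting_id": "s", "observer": 5,
                            "biomass_t": 42.0}])
        assert adjust_school_sizes(df, calib)["biomass_t"].iloc[0] == 42.0

    def test_unknown_observer_is_an_error(self):
        with pytest.raises(CalibrationError, match="without calibration"):
            adjust_school_sizes(pd.DataFrame(
                [{"school_id": "x", "sighting_id": "s", "observer": 99,
                  "biomass_t": 10.0}]), _unit_calib())

    def test_sighting_biomass_sums_schools(self):
        df = pd.DataFrame([
            {"school_id": "a", "sighting_id": "s1", "biomass_t": 40.0},
            {"school_id": "b", "sighting_id": "s1", "biomass_t": 60.0},
            {"school_id": "c", "sighting_id": "s2", "biomass_t": 94.5}])
        out = sighting_biomass(df).set_index("sighting_id")
        assert out.loc["s1", "biomass_t"] == pytest.approx(100.0)
        assert out.loc["s2", "biomass_t"] == pytest.approx(94.5)


def _unit_calib():
    rows = [{"school_id": f"s{i}", "sighting_id": f"s{i}", "observer": o,
             "biomass_t": 50.0} for i in range(20) for o in (5, 7)]
    return fit_size_calibration(pd.DataFrame(rows), reference=5)


def counts_frame(flights):
    """flights: list of (pair, {observer: count})."""
    rows = []
    for i, ((pilot, spotter), cts) in enumerate(flights):
        for obs, n in cts.items():
            rows.append({"year": 1993, "month": 1 + i % 3, "day": 1 + i % 28,
                         "plane": f"F{i}", "pilot": pilot, "spotter": spotter,
                         "observer": obs, "n_sightings": n})
    return pd.DataFrame(rows)


class TestPairEfficiency:
    def test_two_to_one_split_recovers_rate_ratio(self):
        # closed-form oracle for two observers: p_hat = n_A / (n_A + n_B),
        # so the implied rate ratio is p_hat / (1 - p_hat)
        rng = np.random.default_rng(24)
        flights = []
        tot_a = tot_b = 0
        for _ in range(500):
            n = int(rng.poisson(4))
            n_a = int(rng.binomial(n, 2 / 3)) if n else 0
            tot_a += n_a
            tot_b += n - n_a
            flights.append(((5, 7), {5: n_a, 7: n - n_a}))
        eff = fit_pair_efficiency(counts_frame(flights))
        ratio = eff.individual[7] / eff.individual[5]
        oracle = tot_b / tot_a
        assert ratio == pytest.approx(oracle, rel=1e-6)
        assert ratio == pytest.approx(0.5, rel=0.15)

    def test_identical_observers_give_unit_efficiencies(self):
        flights = [((5, 7), {5: 3, 7: 3}), ((5, 4), {5: 2, 4: 2}),
                   ((4, 7), {4: 5, 7: 5})] * 10
        eff = fit_pair_efficiency(counts_frame(flights))
        for v in eff.eff.values():
            assert v == pytest.approx(1.0)

    def test_maximum_is_exactly_one(self, pipeline_result):
        eff = pipeline_result.pair_efficiency
        assert max(eff.eff.values()) == 1.0

    def test_relabeling_flights_leaves_efficiencies_unchanged(self):
        rng = np.random.default_rng(25)
        flights = [((5, 7), {5: int(rng.poisson(3)), 7: int(rng.poisson(2))})
                   for _ in range(60)]
        base = fit_pair_efficiency(counts_frame(flights))
        shuffled = counts_frame(list(reversed(flights)))
        again = fit_pair_efficiency(shuffled)
        for pair, v in base.eff.items():
            assert again.eff[pair] == pytest.approx(v, rel=1e-9)

    def test_disconnected_observer_graph_is_an_error(self):
        flights = [((5, 7), {5: 3, 7: 2})] * 5 + [((3, 11), {3: 2, 11: 4})] * 5
        with pytest.raises(CalibrationError, match="disconnected"):
            fit_pair_efficiency(counts_frame(flights))

    def test_recovery_from_simulated_survey(self, sim, pipeline_result):
        # survey-scale check is coarse (tens of splits per pair); precision
        # of the estimator itself is covered by the closed-form ratio test
        est = pipeline_result.pair_efficiency.eff
        true = sim.truth["pair_efficiencies"]
        common = [p for p in est if tuple(p) in true]
        err = [abs(est[p] - true[tuple(p)]) for p in common]
        assert np.median(err) < 0.3
        assert all(0 < est[p] <= 1 for p in common)
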