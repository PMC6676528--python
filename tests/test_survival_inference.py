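import math

import numpy as np
import pytest

from wgdfrac import (
    Branch,
    Event,
    EventSchedule,
    RateEstimates,
    SpeciationScenario,
    ValidationError,
    doubling,
    estimate_amplification,
    estimate_survival,
    expected_ortholog_pairs,
    expected_paralog_pairs,
    expected_unpaired,
    fractionation_rate,
    rate_consistency_report,
    rates_from_fit,
    scenario_expected_unpaired,
    simulate_ortholog_batch,
    simulate_paralog_batch,
    tripling,
)


class TestFractionationRate:
    def test_full_survival_zero_rate(self):
        assert fractionation_rate(1.0, 30.0, 10.0) == 0.0

    def test_closed_form(self):
        assert fractionation_rate(math.exp(-1.0), 10.0, 0.0) == pytest.approx(0.1, abs=1e-15)

    def test_round_trip_identity(self):
        for u in (0.05, 0.4, 0.99):
            rho = fractionation_rate(u, 45.0, 12.0)
            assert math.exp(-rho * (45.0 - 12.0)) == pytest.approx(u, rel=1e-12)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValidationError):
            fractionation_rate(0.5, 10.0, 10.0)

    def test_rate_estimates_enforce_consistency(self):
        with pytest.raises(ValidationError):
            RateEstimates(("x",), (10.0,), (0.0,), (0.5,), (0.123,))


def skeleton_two_wgd():
    return EventSchedule(
        1,
        (
            Event("wgd", 65.0, doubling(0.5)),
            Event("wgd", 30.0, doubling(0.5)),
            Event("observation", 0.0),
        ),
    )


class TestEstimateSurvival:
    def test_exact_inverse_at_expectation_point(self):
        """Feeding the closed-form expected counts recovers u to 1e-6."""
        truth = EventSchedule(
            1,
            (
                Event("wgd", 65.0, doubling(0.35)),
                Event("wgd", 30.0, doubling(0.55)),
                Event("observation", 0.0),
            ),
        )
        expect = expected_paralog_pairs(truth)
        fit = estimate_survival(
            list(expect.pairs), skeleton_two_wgd(), unpaired=expect.unpaired, seed=1
        )
        assert fit.u["wgd1"] == pytest.approx(0.35, abs=1e-6)
        assert fit.u["wgd2"] == pytest.approx(0.55, abs=1e-6)

    def test_exact_inverse_scenario(self):
        truth = SpeciationScenario(
            1,
            (Event("wgd", 80.0, doubling(0.3)),),
            Event("speciation", 40.0, doubling(0.65)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        expect = expected_ortholog_pairs(truth)
        skeleton = SpeciationScenario(
            1,
            (Event("wgd", 80.0, doubling(0.5)),),
            Event("speciation", 40.0, doubling(0.5)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        fit = estimate_survival(
            list(expect.pairs), skeleton, unpaired=scenario_expected_unpaired(truth), seed=1
        )
        assert fit.u["wgd1"] == pytest.approx(0.3, abs=1e-6)
        assert fit.u["speciation"] == pytest.approx(0.65, abs=1e-6)

    def test_recovery_from_simulated_counts(self):
        """Counts simulated at M1=1000 land within 3 Monte-Carlo standard
        errors, and so do the u estimates (delta method via refit)."""
        truth = SpeciationScenario(
            1000,
            (Event("wgd", 80.0, doubling(0.3)),),
            Event("speciation", 40.0, doubling(0.6)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        batch = simulate_ortholog_batch(truth, 1, seed=4)
        skeleton = SpeciationScenario(
            1,
            (Event("wgd", 80.0, doubling(0.5)),),
            Event("speciation", 40.0, doubling(0.5)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        fit = estimate_survival(
            list(batch.pairs[0]), skeleton, unpaired=float(batch.unpaired[0]), seed=2
        )
        # Monte-Carlo spread of the estimator measured over repeat fits
        reps = simulate_ortholog_batch(truth, 60, seed=5)
        u1s, uss = [], []
        for r in range(60):
            f = estimate_survival(
                list(reps.pairs[r]), skeleton, unpaired=float(reps.unpaired[r]), seed=3,
                n_restarts=2,
            )
            u1s.append(f.u["wgd1"])
            uss.append(f.u["speciation"])
        assert abs(fit.u["wgd1"] - 0.3) <= 3 * np.std(u1s, ddof=1)
        assert abs(fit.u["speciation"] - 0.6) <= 3 * np.std(uss, ddof=1)

    def test_tripling_uses_constrained_u3(self):
        """The tripling fit constrains u3 = u2^2: feeding counts generated
        under that constraint recovers u2 exactly."""
        truth = EventSchedule(
            1,
            (Event("wgd", 80.0, tripling(0.2)), Event("observation", 0.0)),
        )
        assert truth.events[0].survival.u[3] == pytest.approx(0.04)
        expect = expected_paralog_pairs(truth)
        skeleton = EventSchedule(
            1, (Event("wgd", 80.0, tripling(0.5)), Event("observation", 0.0))
        )
        fit = estimate_survival(list(expect.pairs), skeleton, unpaired=expect.unpaired, seed=1)
        assert fit.u["wgd1"] == pytest.approx(0.2, abs=1e-6)
        assert any("u3 = u2^2" in f for f in fit.flags)

    def test_identifiability_guard(self):
        """Two free parameters cannot be estimated from two counts (one
        independent proportion) without the unpaired cell."""
        with pytest.raises(ValidationError, match="independent"):
            estimate_survival([100.0, 50.0], skeleton_two_wgd(), seed=1)

    def test_count_event_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            estimate_survival([100.0], skeleton_two_wgd(), unpaired=10.0, seed=1)


class TestRatesFromFit:
    def test_intervals_and_rates(self):
        truth = EventSchedule(
            1,
            (
                Event("wgd", 65.0, doubling(0.35)),
                Event("wgd", 30.0, doubling(0.55)),
                Event("observation", 0.0),
            ),
        )
        expect = expected_paralog_pairs(truth)
        fit = estimate_survival(list(expect.pairs), skeleton_two_wgd(), unpaired=expect.unpaired)
        est = rates_from_fit(fit)
        assert est.labels == ("wgd1", "wgd2")
        assert est.t_start == (65.0, 30.0)
        assert est.t_end == (30.0, 0.0)
        assert est.rho[0] == pytest.approx(-math.log(0.35) / 35.0, rel=1e-4)
        assert est.rho[1] == pytest.approx(-math.log(0.55) / 30.0, rel=1e-4)

    def test_asymmetric_branches_reported_per_branch(self):
        truth = SpeciationScenario(
            1,
            (Event("wgd", 80.0, doubling(0.3)),),
            Event("speciation", 40.0, doubling(0.65)),
            Branch((Event("wgd", 20.0, doubling(0.7)), Event("observation", 0.0))),
            Branch((Event("observation", 0.0),)),
        )
        expect = expected_ortholog_pairs(truth)
        fit = estimate_survival(
            list(expect.pairs), truth, unpaired=scenario_expected_unpaired(truth)
        )
        est = rates_from_fit(fit)
        assert "speciation:A" in est.labels and "speciation:B" in est.labels
        ia = est.labels.index("speciation:A")
        ib = est.labels.index("speciation:B")
        assert est.t_end[ia] == 20.0 and est.t_end[ib] == 0.0
        assert est.u[ia] == est.u[ib]


class TestAmplification:
    def test_exact_doubling_of_counts(self):
        fit = estimate_amplification([20.0, 40.0, 80.0], [10.0, 20.0, 40.0])
        assert fit.factor == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_outgroup_rejected(self):
        with pytest.raises(ValidationError):
            estimate_amplification([1.0, 2.0], [0.0, 0.0])

    def test_noise_robustness(self):
        rng = np.random.default_rng(6)
        x = np.array([100.0, 220.0, 310.0, 150.0, 510.0])
        y = 1.6 * x * (1 + rng.uniform(-0.05, 0.05, x.size))
        fit = estimate_amplification(y, x)
        assert abs(fit.factor - 1.6) / 1.6 <= 0.05

    def test_recovers_post_speciation_wgd_factor(self):
        """A WGD with u2 = 0.75 in one branch amplifies every ortholog
        category by 1 + u2 = 1.75; the through-origin regression against
        the unamplified scenario recovers it within 3 standard errors."""
        base = dict(
            pre=(Event("wgd", 90.0, tripling(0.25)),),
            spec=Event("speciation", 55.0, doubling(0.6)),
        )
        m1s = (4000, 6000, 8000, 10000)
        xs, ys = [], []
        for j, m1 in enumerate(m1s):
            plain = SpeciationScenario(
                m1, base["pre"], base["spec"],
                Branch((Event("observation", 0.0),)),
                Branch((Event("observation", 0.0),)),
            )
            amped = SpeciationScenario(
                m1, base["pre"], base["spec"],
                Branch((Event("wgd", 20.0, doubling(0.75)), Event("observation", 0.0))),
                Branch((Event("observation", 0.0),)),
            )
            xs.append(simulate_ortholog_batch(plain, 1, seed=10 + j).pairs[0].sum())
            ys.append(simulate_ortholog_batch(amped, 1, seed=50 + j).pairs[0].sum())
        fit = estimate_amplification(ys, xs)
        assert abs(fit.factor - 1.75) <= 3 * max(fit.se, 0.01)


class TestConsistencyReport:
    def _est(self, rho_by_label):
        labels, rho = zip(*rho_by_label.items())
        t0, t1 = (40.0,) * len(labels), (0.0,) * len(labels)
        u = tuple(math.exp(-r * 40.0) for r in rho)
        return RateEstimates(labels, t0, t1, u, rho)

    def test_identical_inputs_zero_spread(self):
        a = self._est({"speciation": 0.02})
        df = rate_consistency_report([a, a])
        assert df.loc[0, "rho_range"] == 0.0
        assert not df.loc[0, "flagged"]

    def test_unequal_rates_flagged(self):
        a = self._est({"speciation": 0.01})
        b = self._est({"speciation": 0.05})
        df = rate_consistency_report([a, b], cv_threshold=0.25)
        assert bool(df.loc[0, "flagged"])

    def test_sampling_noise_not_flagged(self):
        """Comparisons simulated under one true rate stay within sampling
        spread and are not flagged at the default threshold."""
        truth = SpeciationScenario(
            2000,
            (Event("wgd", 80.0, doubling(0.3)),),
            Event("speciation", 40.0, doubling(0.6)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        skeleton = SpeciationScenario(
            1,
            (Event("wgd", 80.0, doubling(0.5)),),
            Event("speciation", 40.0, doubling(0.5)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        ests = []
        for seed in range(5):
            batch = simulate_ortholog_batch(truth, 1, seed=30 + seed)
            fit = estimate_survival(
                list(batch.pairs[0]), skeleton, unpaired=float(batch.unpaired[0]),
                seed=1, n_restarts=3,
            )
            ests.append(rates_from_fit(fit))
        df = rate_consistency_report(ests, cv_threshold=0.25)
        assert not df["flagged"].any()
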