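import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgdfrac import (
    Branch,
    Event,
    EventSchedule,
    SpeciationScenario,
    ValidationError,
    constant_doubling_pair_count,
    doubling,
    enumerate_histories,
    expected_gene_count,
    expected_ortholog_pairs,
    expected_paralog_pairs,
    expected_unpaired,
    history_probability,
    scenario_expected_unpaired,
    tripling,
)

from _oracle import oracle_expectations


def schedule_of(m1, *survivals, t0=100.0):
    events = [
        Event("wgd", t0 - 10.0 * i, d) for i, d in enumerate(survivals)
    ] + [Event("observation", 0.0)]
    return EventSchedule(m1, tuple(events))


class TestGeneCount:
    def test_deterministic_doubling(self):
        assert expected_gene_count(schedule_of(1, doubling(1.0))) == 2.0

    def test_no_wgd_identity(self):
        assert expected_gene_count(EventSchedule(5, (Event("observation", 0.0),))) == 5.0

    def test_two_doublings_product_of_means(self):
        sch = schedule_of(1, doubling(0.3), doubling(0.3))
        assert expected_gene_count(sch) == pytest.approx(1.69, abs=1e-12)

    def test_matches_history_enumeration(self):
        sch = schedule_of(2, doubling(0.3), tripling(0.2, 0.1))
        em = sum(p * m for _, p, m in enumerate_histories(sch))
        assert expected_gene_count(sch) == pytest.approx(em, abs=1e-9)


class TestHistoryProbability:
    def test_single_wgd_terms(self):
        sch = schedule_of(1, doubling(0.6))  # u = (0, 0.4, 0.6)
        assert history_probability(sch, [(0, 1, 0)]) == pytest.approx(0.4)
        assert history_probability(sch, [(0, 0, 1)]) == pytest.approx(0.6)

    def test_multinomial_coefficient(self):
        sch = schedule_of(2, doubling(0.6))
        # M1=2, one gene keeps 1 copy and one keeps 2: C(2;1,1)*0.4*0.6
        assert history_probability(sch, [(0, 1, 1)]) == pytest.approx(0.48)

    @pytest.mark.parametrize(
        "sch",
        [
            schedule_of(1, doubling(0.3), doubling(0.7)),
            schedule_of(2, tripling(0.2, 0.1)),
            schedule_of(2, doubling(0.5, u0=0.1), doubling(0.4)),
        ],
    )
    def test_probabilities_sum_to_one(self, sch):
        total = sum(p for _, p, _ in enumerate_histories(sch))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_inconsistent_table_rejected(self):
        sch = schedule_of(1, doubling(0.6))
        with pytest.raises(ValidationError):
            history_probability(sch, [(0, 2, 0)])  # sums to 2, M1 = 1
        with pytest.raises(ValidationError):
            history_probability(sch, [(0, 1, 0), (0, 1, 0)])  # too many rows


class TestParalogPairs:
    def test_single_deterministic_wgd(self):
        summary = expected_paralog_pairs(schedule_of(1, doubling(1.0)))
        assert summary.pairs == (1.0,)

    @pytest.mark.parametrize("n_events", [2, 3, 4])
    @pytest.mark.parametrize("u", [0.1, 0.5, 0.9])
    def test_constant_doubling_closed_form(self, n_events, u):
        """With equal pair survival u at every doubling,
        E(N_i) = u (1+u)^(2*n_events - i - 1) exactly."""
        sch = schedule_of(1, *[doubling(u)] * n_events)
        summary = expected_paralog_pairs(sch)
        for i, n_i in zip(summary.origins, summary.pairs):
            assert n_i == pytest.approx(constant_doubling_pair_count(n_events, i, u), rel=1e-12)

    def test_theorem_structure_heterogeneous_doublings(self):
        u = [0.2, 0.5, 0.8]
        sch = schedule_of(1, *[doubling(x) for x in u])
        summary = expected_paralog_pairs(sch)
        # E(N_i) = prod_{j<i}(1+u_j) * u_i * prod_{j>i}(1+u_j)^2
        for i in range(3):
            expect = (
                math.prod(1 + x for x in u[:i])
                * u[i]
                * math.prod((1 + x) ** 2 for x in u[i + 1 :])
            )
            assert summary.pairs[i] == pytest.approx(expect, rel=1e-12)

    def test_tripling_closed_form(self):
        u2, u3 = 0.2, 0.04
        sch = schedule_of(1, tripling(u2, u3), tripling(u2, u3))
        summary = expected_paralog_pairs(sch)
        pf, mu = 3 * u3 + u2, 1 + u2 + 2 * u3
        assert summary.pairs[0] == pytest.approx(pf * mu**2, rel=1e-12)
        assert summary.pairs[1] == pytest.approx(mu * pf, rel=1e-12)

    def test_matches_lineage_enumeration_oracle(self):
        for sch in [
            schedule_of(1, doubling(0.3), tripling(0.2, 0.1)),
            schedule_of(2, doubling(0.5, u0=0.1), doubling(0.4)),
            schedule_of(1, tripling(0.3, 0.1), doubling(0.6), doubling(0.2)),
        ]:
            e_m, e_pairs, _ = oracle_expectations(sch)
            summary = expected_paralog_pairs(sch)
            assert expected_gene_count(sch) == pytest.approx(e_m, abs=1e-9)
            for a, b in zip(summary.pairs, e_pairs):
                assert a == pytest.approx(b, abs=1e-9)

    def test_rejects_speciation_schedules(self):
        with pytest.raises(ValidationError):
            EventSchedule(
                1, (Event("speciation", 10.0, doubling(0.5)), Event("observation", 0.0))
            )

    @given(
        base=st.tuples(st.floats(0.05, 0.4), st.floats(0.05, 0.4)),
        bump=st.floats(0.01, 0.2),
        which=st.integers(0, 1),
        k_from=st.integers(0, 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pair_counts_monotone_in_survival(self, base, bump, which, k_from):
        """Moving survival mass upward (u_j -> u_k, j < k) never decreases
        any expected pair count."""
        u0, u2 = 0.1, base[which]
        u1 = 1 - u0 - u2
        # move `bump` of mass from class k_from (0 or 1) up to class 2
        shift = min(bump, (u0 if k_from == 0 else u1) - 1e-9)
        if shift <= 0:
            return
        lo = [u0, u1, u2]
        hi = list(lo)
        hi[k_from] -= shift
        hi[2] += shift
        other = doubling(base[1 - which])
        from wgdfrac import SurvivalDistribution

        sch_lo = schedule_of(1, SurvivalDistribution(2, tuple(lo)), other)
        sch_hi = schedule_of(1, SurvivalDistribution(2, tuple(hi)), other)
        lo_pairs = expected_paralog_pairs(sch_lo).pairs
        hi_pairs = expected_paralog_pairs(sch_hi).pairs
        for a, b in zip(hi_pairs, lo_pairs):
            assert a >= b - 1e-12


class TestUnpaired:
    def test_zero_when_any_u1_zero(self):
        assert expected_unpaired(schedule_of(10, doubling(1.0), doubling(0.5))) == 0.0

    def test_product_form(self):
        sch = schedule_of(1000, doubling(0.3), doubling(0.5))  # u1 = 0.7, 0.5
        assert expected_unpaired(sch) == pytest.approx(350.0)

    def test_no_wgd_returns_m1(self):
        assert expected_unpaired(EventSchedule(7, (Event("observation", 0.0),))) == 7.0

    def test_matches_oracle_without_lineage_extinction(self):
        sch = schedule_of(2, doubling(0.3), tripling(0.2, 0.05))
        _, _, e_unpaired = oracle_expectations(sch)
        assert expected_unpaired(sch) == pytest.approx(e_unpaired, abs=1e-9)

    def test_lower_bound_with_lineage_extinction(self):
        # with u0 > 0 at a later event, extinct side branches leave extra
        # unpaired genes that the product formula does not count
        sch = schedule_of(1, doubling(0.4), doubling(0.5, u0=0.2))
        _, _, e_unpaired = oracle_expectations(sch)
        assert expected_unpaired(sch) < e_unpaired


class TestOrthologPairs:
    def test_full_survival_structure(self):
        """Two triplings then a speciation with full survival: every gene
        at speciation yields exactly one s-origin ortholog pair."""
        scen = SpeciationScenario(
            1,
            (Event("wgd", 80, tripling(1.0, 0.0)), Event("wgd", 60, tripling(1.0, 0.0))),
            Event("speciation", 40, doubling(1.0)),
            Branch((Event("observation", 0.0),)),
            Branch((Event("observation", 0.0),)),
        )
        summary = expected_ortholog_pairs(scen)
        m_s = 4.0  # 2 triplings with exactly two survivors each
        assert summary.pairs[-1] == pytest.approx(m_s)

    def test_empty_amplification_quarter_constant(self):
        """With no post-speciation WGDs and independent copy survival 1,
        E(O_s) = 1/4 * prod(1 + u(j)) * F_A * F_B with F = (1 + 1) = 2."""
        scen = SpeciationScenario(
            1,
            (Event("wgd", 80, doubling(0.4)),),
            Event("speciation", 40),
            Branch((Event("observation", 0.0),), copy_survival=1.0),
            Branch((Event("observation", 0.0),), copy_survival=1.0),
        )
        summary = expected_ortholog_pairs(scen)
        assert summary.pairs[-1] == pytest.approx(0.25 * 1.4 * 2 * 2)

    def test_doubling_formulas_with_post_speciation_wgd(self):
        """s=2; pre-WGD u2=0.4; one WGD in A (u2=0.5), none in B."""
        ua_s, ub_s = 0.3, 0.45
        scen = SpeciationScenario(
            1,
            (Event("wgd", 80, doubling(0.4)),),
            Event("speciation", 40),
            Branch(
                (Event("wgd", 20, doubling(0.5)), Event("observation", 0.0)),
                copy_survival=ua_s,
            ),
            Branch((Event("observation", 0.0),), copy_survival=ub_s),
        )
        summary = expected_ortholog_pairs(scen)
        fa = (1 + ua_s) * (1 + 0.5)
        fb = 1 + ub_s
        assert summary.pairs[0] == pytest.approx(0.5 * 0.4 * fa * fb, rel=1e-12)
        assert summary.pairs[1] == pytest.approx(0.25 * 1.4 * fa * fb, rel=1e-12)

    def test_coupled_tripling_formulas(self, tripling_speciation):
        u2, u3, us = 0.2, 0.04, 0.7
        summary = expected_ortholog_pairs(tripling_speciation)
        assert summary.pairs[0] == pytest.approx(0.5 * (3 * u3 + u2) * (1 + us) ** 2, rel=1e-12)
        assert summary.pairs[1] == pytest.approx(us * (1 + 2 * u3 + u2), rel=1e-12)

    def test_scenario_unpaired_generating_function(self, tripling_speciation):
        # alpha = u1s/2, G'(x) = u1 + 2 u2 x + 3 u3 x^2 for one tripling
        u2, u3, us = 0.2, 0.04, 0.7
        alpha = (1 - us) / 2
        gp = (1 - u2 - u3) + 2 * u2 * alpha + 3 * u3 * alpha**2
        assert scenario_expected_unpaired(tripling_speciation) == pytest.approx(
            2 * alpha * gp, rel=1e-12
        )

    def test_report_serialization(self, tripling_speciation):
        df = expected_ortholog_pairs(tripling_speciation).to_frame()
        assert list(df.columns) == ["origin_event", "time_My", "expected_pairs", "kind"]
        assert set(df["kind"]) == {"ortholog"}
        assert list(df["origin_event"]) == [1, 2]
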