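import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from pvsignal.contingency import ContingencyTable
from pvsignal.signal_stats import (
    DEFAULT_PRIORS,
    SignalResult,
    classify_signal,
    compute_signal,
    ebgm_stats,
    ic_stats,
    prr_stats,
    rank_signals,
    ror_stats,
    round_half_up,
)

from tests.naive_oracle import naive_all

T = ContingencyTable("x", 10, 90, 100, 9900)

cells = st.integers(min_value=1, max_value=5000)


@st.composite
def tables(draw):
    return ContingencyTable(
        "t", draw(cells), draw(cells), draw(cells), draw(cells)
    )


class TestRor:
    def test_reference_table(self):
        # frozen from independent hand evaluation of the closed form
        r = ror_stats(T)
        assert r.ror == pytest.approx(11.0)
        assert r.se_log == pytest.approx(0.348155, abs=1e-6)
        assert r.ci_low == pytest.approx(5.5595, abs=1e-3)
        assert r.ci_high == pytest.approx(21.7645, abs=1e-3)

    def test_independence_table_symmetric_about_one(self):
        r = ror_stats(ContingencyTable("x", 1, 1, 1, 1))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)

    def test_log_symmetry_recovers_published_upper_bound(self):
        # published estimate 80.255, lower 25.750 -> upper 250.13
        assert 80.255**2 / 25.750 == pytest.approx(250.135, rel=2e-4)


class TestPrr:
    def test_reference_table(self):
        pearson = prr_stats(T, "pearson")
        yates = prr_stats(T, "yates")
        assert pearson.prr == pytest.approx(10.0)
        assert pearson.chi2 == pytest.approx(74.4472, abs=1e-3)
        assert yates.chi2 == pytest.approx(66.3269, abs=1e-3)

    @pytest.mark.parametrize("variant,correction", [("pearson", False),
                                                    ("yates", True)])
    def test_chi2_matches_generic_2x2_routine(self, variant, correction):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable("x", int(a), int(b), int(c), int(d))
            ours = prr_stats(t, variant).chi2
            ref = scipy_stats.chi2_contingency(
                [[a, b], [c, d]], correction=correction
            ).statistic
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_independence_implies_unit_prr(self):
        t = ContingencyTable("x", 4, 8, 12, 24)  # ad = bc
        assert prr_stats(t).prr == pytest.approx(1.0)
        assert ror_stats(t).ror == pytest.approx(1.0)


class TestIcEbgm:
    def test_reference_table(self):
        ic = ic_stats(T)
        eb = ebgm_stats(T)
        # frozen from independent evaluation: ebgm = 10*10100/(100*110)
        assert eb.ebgm == pytest.approx(9.181818, abs=1e-5)
        assert ic.ic == pytest.approx(math.log2(9.181818), abs=1e-5)
        assert eb.ebgm05 == pytest.approx(5.187493, abs=1e-5)

    def test_independence_gives_zero_ic_unit_ebgm(self):
        t = ContingencyTable("x", 4, 8, 12, 24)
        assert ic_stats(t).ic == pytest.approx(0.0, abs=1e-12)
        assert ebgm_stats(t).ebgm == pytest.approx(1.0)

    def test_crude_ic_matches_published_log2_ebgm(self):
        assert math.log2(65.708) == pytest.approx(6.038, abs=5e-4)

    def test_published_ebgm05_recovered_from_ror_ci(self):
        se = math.log(80.255 / 25.750) / 1.96
        assert 79.533 * math.exp(-1.64 * se) == pytest.approx(30.722, rel=5e-4)

    @given(tables())
    @settings(max_examples=200, deadline=None)
    def test_ic_is_log2_ebgm_exactly(self, t):
        assert ic_stats(t).ic == pytest.approx(
            math.log2(ebgm_stats(t).ebgm), rel=1e-12, abs=1e-12
        )

    def test_posterior_moments_converge_to_crude_ic(self):
        # scale a fixed table up; E(IC) -> IC and V(IC) -> 0
        base = (3, 17, 40, 940)
        gaps, variances = [], []
        for k in (1, 100, 10_000):
            t = ContingencyTable("x", *(k * v for v in base))
            r = ic_stats(t, DEFAULT_PRIORS)
            gaps.append(abs(r.e_ic - r.ic))
            variances.append(r.v_ic)
        assert gaps[0] > gaps[1] > gaps[2]
        assert variances[0] > variances[1] > variances[2]
        # V(IC) decays like 1/(scale * a): four orders of magnitude down
        assert gaps[2] < 1e-3 and variances[2] < variances[0] * 1e-3


class TestInvariants:
    @given(tables())
    @settings(max_examples=300, deadline=None)
    def test_ordering_ror_prr_ebgm(self, t):
        ror = ror_stats(t).ror
        prr = prr_stats(t).prr
        ebgm = ebgm_stats(t).ebgm
        tol = 1e-9
        if ror > 1 + tol:
            assert ror >= prr - tol >= ebgm - 2 * tol
        elif ror < 1 - tol:
            assert ror <= prr + tol <= ebgm + 2 * tol
        else:  # independence: all equal 1
            assert prr == pytest.approx(1.0) and ebgm == pytest.approx(1.0)

    @given(tables())
    @settings(max_examples=200, deadline=None)
    def test_wald_interval_log_symmetry(self, t):
        r = ror_stats(t)
        assert r.ci_low * r.ci_high == pytest.approx(r.ror**2, rel=1e-9)
        p = prr_stats(t)
        assert p.ci_low * p.ci_high == pytest.approx(p.prr**2, rel=1e-9)

    @given(tables())
    @settings(max_examples=100, deadline=None)
    def test_transposing_drug_and_event_leaves_ror_unchanged(self, t):
        swapped = ContingencyTable("t", t.a, t.c, t.b, t.d)
        assert ror_stats(swapped).ror == pytest.approx(
            ror_stats(t).ror, rel=1e-12
        )

    def test_oracle_equivalence_random_tables(self):
        """The pipeline agrees with a naive independent implementation of
        every printed formula to 12 significant digits."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 10_000, size=4))
            t = ContingencyTable("x", a, b, c, d)
            ref = naive_all(a, b, c, d)
            r = compute_signal(t, chi2_variant="yates")
            for ours, theirs in [
                (r.ror, ref["ror"]), (r.ror_ci_low, ref["ror_low"]),
                (r.ror_ci_high, ref["ror_high"]),
                (r.prr, ref["prr"]), (r.prr_ci_low, ref["prr_low"]),
                (r.prr_ci_high, ref["prr_high"]),
                (r.chi2, ref["chi2_yates"]),
                (r.ic, ref["ic"]), (r.e_ic, ref["e_ic"]),
                (r.v_ic, ref["v_ic"]), (r.ic_025, ref["ic_025"]),
                (r.ebgm, ref["ebgm"]), (r.ebgm05, ref["ebgm05"]),
            ]:
                assert ours == pytest.approx(theirs, rel=1e-12, abs=1e-12)


class TestClassification:
    def _result(self, **kw):
        base = dict(drug="x", a=5, b=10, c=50, d=1000,
                    ror=10, ror_ci_low=2.0, prr=9, prr_ci_low=2.0,
                    ic_025=2.0, ebgm05=3.0)
        base.update(kw)
        return SignalResult(**{k: v for k, v in base.items()})

    def test_high_tier_joint_positive(self):
        r = classify_signal(
            self._result(a=3, ror_ci_low=25.750, ic_025=4.640, ebgm05=30.722)
        )
        assert r.joint_signal and r.tier == "high"

    @pytest.mark.parametrize(
        "ic025, tier",
        [(-0.5, "none"), (0.0, "none"), (0.190, "low"), (1.5, "low"),
         (1.719, "medium"), (3.0, "medium"), (3.065, "high")],
    )
    def test_ic025_risk_tiers(self, ic025, tier):
        assert classify_signal(self._result(ic_025=ic025)).tier == tier

    def test_report_floor_blocks_ror_and_prr_flags(self):
        r = classify_signal(self._result(a=2))
        assert not r.flags["ror"] and not r.flags["prr"]
        assert not r.joint_signal

    def test_ebgm05_threshold(self):
        assert not classify_signal(self._result(ebgm05=2.0)).flags["mgps"]
        assert classify_signal(self._result(ebgm05=2.01)).flags["mgps"]

    def test_joint_is_conjunction(self):
        r = classify_signal(self._result(ic_025=-1.0))
        assert not r.joint_signal and r.flags["ror"] and r.flags["mgps"]


class TestRanking:
    def _r(self, drug, ic025, ror=1.0):
        return SignalResult(drug=drug, a=3, b=1, c=1, d=1,
                            ic_025=ic025, ror=ror)

    def test_descending_ic025_matches_published_order(self):
        ranked = rank_signals([
            self._r("tadalafil", 3.488), self._r("mirabegron", 4.640),
            self._r("raloxifene", 4.370),
        ])
        assert [r.drug for r in ranked] == [
            "mirabegron", "raloxifene", "tadalafil"
        ]

    def test_tie_broken_by_ror_then_name(self):
        ranked = rank_signals([
            self._r("b", 2.0, ror=5), self._r("a", 2.0, ror=9),
            self._r("c", 2.0, ror=5),
        ])
        assert [r.drug for r in ranked] == ["a", "b", "c"]

    def test_input_order_irrelevant(self):
        items = [self._r(d, ic) for d, ic in
                 [("a", 1.0), ("b", 3.0), ("c", 2.0), ("d", 2.5)]]
        expected = [r.drug for r in rank_signals(items)]
        assert [r.drug for r in rank_signals(items[::-1])] == expected


def test_round_half_up_report_convention():
    assert round_half_up(2.0005) == 2.001
    assert round_half_up(2.0004) == 2.000
    assert round_half_up(-1.2345) == -1.235
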