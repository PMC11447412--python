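"""Closed-form dimer composition and hypothesis-prediction arithmetic."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from keapsense import (
    DimerPopulation,
    HeterodimerMode,
    Hypothesis,
    InactivationSetting,
    Selection,
    dimer_composition,
    evaluate_hypotheses,
    heterodimer_inactivated_fraction,
    infer_homodimer_inactivation,
    predict_total_activity,
)
from conftest import make_estimate

POP_HET = DimerPopulation(0.25, 0.5, 0.25)


class TestDimerComposition:
    @pytest.mark.parametrize(
        "w, expected",
        [
            (0.5, (0.25, 0.50, 0.25)),
            (1.0, (1.0, 0.0, 0.0)),
            (0.3, (0.09, 0.42, 0.49)),
            (0.0, (0.0, 0.0, 1.0)),
        ],
    )
    def test_random_pairing_fractions(self, w, expected):
        pop = dimer_composition(w)
        assert (pop.f_wt_homo, pop.f_het, pop.f_mut_homo) == pytest.approx(expected)

    @pytest.mark.parametrize("w", [-0.01, 1.01, float("nan")])
    def test_out_of_range_fraction_rejected(self, w):
        with pytest.raises(ValueError):
            dimer_composition(w)

    @given(num=st.integers(0, 60), den=st.integers(1, 60))
    @settings(max_examples=80, deadline=None)
    def test_matches_ordered_pair_enumeration(self, num, den):
        """Enumerate all ordered monomer pairs from a finite pool at a rational
        WT fraction; collapsing symmetric heterodimers must reproduce the
        closed-form composition, which in turn must sum to one."""
        w = Fraction(min(num, den), den)
        pool = ["W"] * w.numerator + ["M"] * (w.denominator - w.numerator)
        n = len(pool)
        counts = {"WW": 0, "MW": 0, "MM": 0}
        for a in pool:
            for b in pool:
                counts["".join(sorted(a + b))] += 1
        pop = dimer_composition(float(w))
        assert pop.f_wt_homo == pytest.approx(counts["WW"] / n**2, abs=1e-12)
        assert pop.f_het == pytest.approx(counts["MW"] / n**2, abs=1e-12)
        assert pop.f_mut_homo == pytest.approx(counts["MM"] / n**2, abs=1e-12)
        assert pop.f_wt_homo + pop.f_het + pop.f_mut_homo == pytest.approx(1.0, abs=1e-12)


class TestHomodimerInactivation:
    @pytest.mark.parametrize("activity, expected", [(0.26, 0.74), (1.0, 0.0), (0.5, 0.5)])
    def test_complement(self, activity, expected):
        assert infer_homodimer_inactivation(activity) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infer_homodimer_inactivation(1.2)


class TestHeterodimerInactivatedFraction:
    def test_paper_linear_halving(self):
        s = InactivationSetting(0.74, Hypothesis.MONOMER, HeterodimerMode.PAPER_LINEAR)
        assert heterodimer_inactivated_fraction(s) == pytest.approx(0.37)

    @pytest.mark.parametrize("mode", list(HeterodimerMode))
    def test_dimer_hypothesis_heterodimers_untouchable(self, mode):
        s = InactivationSetting(0.74, Hypothesis.DIMER, mode)
        assert heterodimer_inactivated_fraction(s) == 0.0

    def test_binomial_matches_bisection_oracle(self):
        """The per-monomer probability must solve 1 - (1-p)^2 = f_inact; the
        oracle solves it numerically rather than via the closed form."""
        p_oracle = brentq(lambda p: 1 - (1 - p) ** 2 - 0.74, 0.0, 1.0, xtol=1e-12)
        s = InactivationSetting(0.74, Hypothesis.MONOMER, HeterodimerMode.BINOMIAL)
        assert heterodimer_inactivated_fraction(s) == pytest.approx(p_oracle, abs=1e-9)
        assert heterodimer_inactivated_fraction(s) == pytest.approx(0.490098, abs=1e-6)


class TestPredictTotalActivity:
    def test_monomer_linear_reproduces_63(self):
        pred = predict_total_activity(
            POP_HET, InactivationSetting(0.74, Hypothesis.MONOMER)
        )
        assert pred.total_activity == pytest.approx(0.63)
        assert pred.contrib_mut_homo == pytest.approx(0.25)
        assert pred.contrib_wt_homo == pytest.approx(0.065)
        assert pred.contrib_het == pytest.approx(0.315)

    def test_dimer_reproduces_815(self):
        pred = predict_total_activity(
            POP_HET, InactivationSetting(0.74, Hypothesis.DIMER)
        )
        assert pred.total_activity == pytest.approx(0.815)
        assert (pred.contrib_mut_homo, pred.contrib_wt_homo, pred.contrib_het) == (
            pytest.approx(0.25),
            pytest.approx(0.065),
            pytest.approx(0.50),
        )

    def test_monomer_binomial(self):
        pred = predict_total_activity(
            POP_HET,
            InactivationSetting(0.74, Hypothesis.MONOMER, HeterodimerMode.BINOMIAL),
        )
        assert pred.total_activity == pytest.approx(0.569951, abs=1e-6)

    @given(
        w=st.floats(0, 1),
        hyp=st.sampled_from(list(Hypothesis)),
        mode=st.sampled_from(list(HeterodimerMode)),
    )
    @settings(max_examples=60, deadline=None)
    def test_no_stress_means_full_activity(self, w, hyp, mode):
        pred = predict_total_activity(
            dimer_composition(w), InactivationSetting(0.0, hyp, mode)
        )
        assert pred.total_activity == pytest.approx(1.0, abs=1e-12)

    @given(
        w=st.floats(0.01, 0.99),
        f=st.floats(0.001, 1.0),
        mode=st.sampled_from(list(HeterodimerMode)),
    )
    @settings(max_examples=100, deadline=None)
    def test_monomer_predicts_less_than_dimer(self, w, f, mode):
        """With any heterodimers present and nonzero stress, the monomer
        hypothesis must predict strictly lower total activity."""
        pop = dimer_composition(w)
        p_mono = predict_total_activity(pop, InactivationSetting(f, Hypothesis.MONOMER, mode))
        p_dim = predict_total_activity(pop, InactivationSetting(f, Hypothesis.DIMER, mode))
        assert p_mono.total_activity < p_dim.total_activity

    @given(
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
        hyp=st.sampled_from(list(Hypothesis)),
        mode=st.sampled_from(list(HeterodimerMode)),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_stress(self, f1, f2, hyp, mode):
        lo, hi = sorted((f1, f2))
        a_hi = predict_total_activity(POP_HET, InactivationSetting(lo, hyp, mode))
        a_lo = predict_total_activity(POP_HET, InactivationSetting(hi, hyp, mode))
        assert a_lo.total_activity <= a_hi.total_activity + 1e-12

    @given(f=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_binomial_monomer_never_exceeds_linear(self, f):
        """1 - sqrt(1-f) >= f/2 on [0,1], so the binomial heterodimer term is
        at least as inactivating as the halving rule."""
        lin = predict_total_activity(
            POP_HET, InactivationSetting(f, Hypothesis.MONOMER, HeterodimerMode.PAPER_LINEAR)
        )
        binom = predict_total_activity(
            POP_HET, InactivationSetting(f, Hypothesis.MONOMER, HeterodimerMode.BINOMIAL)
        )
        assert binom.total_activity <= lin.total_activity + 1e-12


class TestEvaluateHypotheses:
    def test_estimate_62_pm_13_selects_monomer(self):
        est = make_estimate(0.62, 0.13)
        v = evaluate_hypotheses(POP_HET, 0.74, est)
        assert v.prediction_monomer == pytest.approx(0.63)
        assert v.prediction_dimer == pytest.approx(0.815)
        assert v.within_ci[Hypothesis.MONOMER] and not v.within_ci[Hypothesis.DIMER]
        assert v.selected is Selection.MONOMER

    def test_wide_interval_selects_both(self):
        v = evaluate_hypotheses(POP_HET, 0.74, make_estimate(0.70, 0.20))
        assert v.selected is Selection.BOTH

    def test_far_interval_selects_neither(self):
        v = evaluate_hypotheses(POP_HET, 0.74, make_estimate(0.30, 0.05))
        assert v.selected is Selection.NEITHER

    def test_degenerate_interval_rejected(self):
        est = make_estimate(0.62, 0.0)
        object.__setattr__(est, "ci_low", 0.70)  # force low > high
        with pytest.raises(ValueError, match="degenerate"):
            evaluate_hypotheses(POP_HET, 0.74, est)


def test_population_invariants_enforced():
    with pytest.raises(ValueError):
        DimerPopulation(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        DimerPopulation(-0.1, 0.6, 0.5)


def test_contribution_breakdown_sums_to_total():
    for f in (0.1, 0.5, 0.9):
        for hyp in Hypothesis:
            for mode in HeterodimerMode:
                pred = predict_total_activity(POP_HET, InactivationSetting(f, hyp, mode))
                total = pred.contrib_mut_homo + pred.contrib_wt_homo + pred.contrib_het
                assert math.isclose(pred.total_activity, total, abs_tol=1e-12)
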