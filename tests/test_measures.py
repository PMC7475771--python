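import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, spearmanr

from unseen.measures import (
    CR,
    FA,
    HIT,
    ILLOGICAL,
    MISS,
    SCHEMES,
    UNCLASSIFIED,
    SdtCounts,
    br,
    classify_frame,
    classify_trial,
    dprime_c,
    measure_table,
    pcm,
    pcu,
    pr,
    rates,
)
from unseen.observer import ObserverParams, simulate_responses
from unseen.trials import DesignSpec, generate_design

from conftest import make_trials

# The seven defined rows of the primary allocation, verbatim.
PRIMARY_ALLOCATION = [
    ("arrow_left", "yes", "yes", HIT),
    ("arrow_left", "no", "no", MISS),
    ("non_arrow", "yes", "yes", FA),
    ("non_arrow", "yes", "no", CR),
    ("absent", "yes", "yes", FA),
    ("absent", "yes", "no", FA),
    ("absent", "no", "no", CR),
]


class TestClassification:
    @pytest.mark.parametrize("stimulus,something,arrow,expected", PRIMARY_ALLOCATION)
    def test_primary_allocation_rows(self, stimulus, something, arrow, expected):
        assert classify_trial(stimulus, something, arrow, "PrC") == expected
        # right arrows classify identically to left arrows
        if stimulus == "arrow_left":
            assert classify_trial("arrow_right", something, arrow, "PrC") == expected

    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("stimulus", ["arrow_left", "non_arrow", "absent"])
    def test_illogical_under_every_scheme(self, scheme, stimulus):
        assert classify_trial(stimulus, "no", "yes", scheme) == ILLOGICAL

    def test_rows_absent_from_allocation_are_unclassified(self):
        assert classify_trial("arrow_left", "yes", "no", "PrC") == UNCLASSIFIED
        assert classify_trial("non_arrow", "no", "no", "PrC") == UNCLASSIFIED

    def test_permissive_completion(self):
        assert classify_trial("arrow_left", "yes", "no", "PrC", strict_table1=False) == MISS
        assert classify_trial("non_arrow", "no", "no", "PrC", strict_table1=False) == CR

    def test_single_question_schemes(self):
        # Arrow question: arrow stimuli are signal, absent supplies FAs.
        assert classify_trial("arrow_right", "yes", "yes", "PrA") == HIT
        assert classify_trial("arrow_right", "no", "no", "PrA") == MISS
        assert classify_trial("absent", "yes", "yes", "PrA") == FA
        assert classify_trial("absent", "no", "no", "PrA") == CR
        assert classify_trial("non_arrow", "yes", "yes", "PrA") == UNCLASSIFIED
        # Something question: arrow and non-arrow both signal.
        assert classify_trial("non_arrow", "yes", "no", "PrS") == HIT
        assert classify_trial("non_arrow", "no", "no", "PrS") == MISS
        assert classify_trial("absent", "yes", "no", "PrS") == FA
        assert classify_trial("absent", "no", "no", "PrS") == CR

    @settings(deadline=None)
    @given(
        stimulus=st.sampled_from(["arrow_left", "arrow_right", "non_arrow", "absent"]),
        something=st.sampled_from(["yes", "no"]),
        arrow=st.sampled_from(["yes", "no"]),
        scheme=st.sampled_from(SCHEMES),
        strict=st.booleans(),
    )
    def test_totality(self, stimulus, something, arrow, scheme, strict):
        """Every response combination maps to exactly one class label."""
        label = classify_trial(stimulus, something, arrow, scheme, strict)
        assert label in {HIT, MISS, FA, CR, UNCLASSIFIED, ILLOGICAL}
        if arrow == "yes" and something == "no":
            assert label == ILLOGICAL

    def test_vectorized_matches_scalar(self, small_cohort):
        sub = small_cohort.head(500)
        for scheme in SCHEMES:
            vec = classify_frame(sub, scheme)
            scalar = [
                classify_trial(r.stimulus, r.resp_something, r.resp_arrow, scheme)
                for r in sub.itertuples()
            ]
            assert list(vec) == scalar


class TestPrBr:
    def test_rates_exact(self):
        assert rates(SdtCounts(8, 2, 3, 7)) == (
            float(Fraction(8, 10)),
            float(Fraction(3, 10)),
        )
        assert rates(SdtCounts(0, 10, 0, 10)) == (0.0, 0.0)
        assert rates(SdtCounts(5, 0, 0, 5)) == (1.0, 0.0)

    def test_empty_denominator_flags_undefined(self):
        hr, far = rates(SdtCounts(0, 0, 3, 7))
        assert math.isnan(hr) and far == 0.3

    def test_no_smoothing_exact_rationals(self):
        """Pr and Br are pure arithmetic: Fraction in, Fraction out."""
        hr, far = Fraction(4, 5), Fraction(3, 10)
        assert pr(hr, far) == Fraction(1, 2)
        assert br(far, pr(hr, far)) == Fraction(3, 5)
        assert pr(Fraction(1), Fraction(0)) == 1
        assert br(Fraction(0), Fraction(1, 3)) == 0

    def test_br_undefined_at_ceiling(self):
        assert math.isnan(br(0.2, 1.0))

    def test_pr_symmetry(self):
        for x in (0.0, 0.25, 1.0):
            assert pr(x, x) == 0.0

    @settings(deadline=None)
    @given(
        hr=st.floats(0, 1), far=st.floats(0, 1),
        bump=st.floats(1e-6, 0.5),
    )
    def test_pr_monotone(self, hr, far, bump):
        if hr + bump <= 1:
            assert pr(hr + bump, far) > pr(hr, far)
        if far + bump <= 1:
            assert pr(hr, far + bump) < pr(hr, far)

    @settings(deadline=None)
    @given(far=st.floats(0, 0.9), prv=st.floats(-1, 0.99), bump=st.floats(1e-6, 0.1))
    def test_br_monotone_in_far_at_fixed_pr(self, far, prv, bump):
        assert br(far + bump, prv) > br(far, prv)


class TestPcuPcm:
    def test_pcu_example(self):
        rows = [
            {"stimulus": "arrow_left", "resp_direction": "left"}
            if i < 7
            else {"stimulus": "arrow_left", "resp_direction": "right"}
            for i in range(10)
        ]
        value, n = pcu(make_trials(rows))
        assert (value, n) == (0.7, 10)

    def test_pcu_requires_double_denial_of_arrow_trials(self):
        rows = [
            {"stimulus": "arrow_left", "resp_arrow": "yes", "resp_something": "yes"},
            {"stimulus": "absent"},  # double denied but no truth value
        ]
        value, n = pcu(make_trials(rows))
        assert math.isnan(value) and n == 0

    def test_pcm_examples(self):
        aware_wrong = {
            "stimulus": "arrow_left", "resp_arrow": "yes",
            "resp_something": "yes", "resp_direction": "right",
        }
        aware_right = {**aware_wrong, "resp_direction": "left"}
        unseen = {"stimulus": "arrow_left"}
        df = make_trials([aware_wrong] * 2 + [aware_right] * 4 + [unseen] * 90)
        value, n = pcm(df)
        assert (value, n) == (2 / 96, 96)
        # perfect discrimination: numerator empty but defined
        df2 = make_trials([aware_right] * 96)
        assert pcm(df2) == (0.0, 96)
        # no arrow trials at all: undefined
        value, n = pcm(make_trials([{"stimulus": "absent"}]))
        assert math.isnan(value) and n == 0


class TestDprime:
    def test_equal_rates_give_zero(self):
        d, c = dprime_c(SdtCounts(6, 14, 3, 7))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_quantiles(self):
        d, c = dprime_c(SdtCounts(8, 2, 3, 7))
        assert d == pytest.approx(norm.ppf(0.8) - norm.ppf(0.3), rel=1e-12)
        assert c == pytest.approx(-0.5 * (norm.ppf(0.8) + norm.ppf(0.3)), rel=1e-12)

    def test_extreme_rates_clamped_finite(self):
        d, c = dprime_c(SdtCounts(10, 0, 0, 10))
        assert math.isfinite(d) and math.isfinite(c)
        assert d == pytest.approx(norm.ppf(1 - 1 / 20) - norm.ppf(1 / 20), rel=1e-12)


class TestMeasureTable:
    def test_cell_census(self, small_cohort):
        one = small_cohort[small_cohort["participant_id"] == "P01"]
        table = measure_table(one, ["PrC", "BrC", "PcU", "PCm", "dprime", "c"])
        assert len(table) == 2 * 5 * 6
        assert table.groupby("measure", observed=True).size().eq(10).all()

    def test_pcu_n_counts_qualifying_trials(self, small_cohort):
        table = measure_table(small_cohort, ["PcU"])
        cell = small_cohort[
            (small_cohort["participant_id"] == "P01")
            & (small_cohort["tms_mode"] == "sham")
            & (small_cohort["tms_time"] == "BIP_only")
        ]
        manual = (
            cell["stimulus"].isin(["arrow_left", "arrow_right"])
            & (cell["resp_arrow"] == "no")
            & (cell["resp_something"] == "no")
        ).sum()
        row = table[
            (table["participant_id"] == "P01")
            & (table["tms_mode"] == "sham")
            & (table["tms_time"] == "BIP_only")
        ].iloc[0]
        assert row["n"] == manual

    def test_idempotent(self, small_cohort):
        a = measure_table(small_cohort, ["PrC", "PcU"])
        b = measure_table(small_cohort, ["PrC", "PcU"])
        pd.testing.assert_frame_equal(a, b)

    def test_matches_cellwise_hand_computation(self, small_cohort):
        from unseen.measures import sdt_counts
        from unseen.trials import is_illogical

        table = measure_table(small_cohort, ["PrC"]).set_index(
            ["participant_id", "tms_mode", "tms_time"]
        )
        cell = small_cohort[
            (small_cohort["participant_id"] == "P03")
            & (small_cohort["tms_mode"] == "active")
            & (small_cohort["tms_time"] == "E30_BIP")
        ]
        counts = sdt_counts(cell[~is_illogical(cell)], "PrC")
        hr, far = rates(counts)
        assert table.loc[("P03", "active", "E30_BIP"), "value"] == pytest.approx(
            hr - far
        )


def test_prc_tracks_dprime_across_observers():
    """Across simulated equal-variance Gaussian observers the non-parametric
    sensitivity measure rank-orders observers like parametric d'."""
    rng = np.random.default_rng(42)
    design = generate_design(DesignSpec(blocks_active=2, blocks_sham=2, seed=3))
    prcs, dprimes = [], []
    for strength in np.linspace(0.6, 3.2, 24):
        params = ObserverParams(
            signal_strength=strength,
            tms_effects={},
            lapse_rate=0.0,
        )
        trials = simulate_responses(design, params, rng)
        table = measure_table(trials, ["PrC", "dprime"])
        pooled = table.groupby("measure", observed=True)["value"].mean()
        prcs.append(pooled["PrC"])
        dprimes.append(pooled["dprime"])
    rho = spearmanr(prcs, dprimes).statistic
    assert rho > 0.9
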