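import math

import numpy as np
import pandas as pd
import pytest

from unseen.inference import (
    AnalysisConfig,
    early_late_contrast,
    fine_contrast,
    one_sample_t,
    paired_t,
    run_report,
    sham_normalize,
    within_subject_se,
)
from unseen.measures import measure_table
from unseen.trials import TMS_MODES, TMS_TIMES


def cells_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "tms_mode", "tms_time", "measure", "value", "n",
                       "defined"]
    )


def delta_frame(entries):
    """entries: {participant: {time: delta}} for one measure."""
    rows = []
    for pid, times in entries.items():
        for t, d in times.items():
            rows.append(dict(participant_id=pid, tms_time=t, measure="PrC",
                             delta=d, defined=not (d is None or math.isnan(d))))
    df = pd.DataFrame(rows)
    df["delta"] = df["delta"].astype(float)
    return df


class TestShamNormalize:
    def test_active_minus_sham(self):
        cells = cells_frame([
            ("P1", "active", "BIP_only", "PrC", 0.6, 100, True),
            ("P1", "sham", "BIP_only", "PrC", 0.7, 100, True),
        ])
        out = sham_normalize(cells)
        assert out.loc[0, "delta"] == pytest.approx(-0.1)

    def test_identical_tables_give_zero(self, small_cohort):
        cells = measure_table(small_cohort, ["PrC"])
        sham_as_active = cells.copy()
        # collapse: make active a copy of sham
        sham_rows = cells[cells["tms_mode"] == "sham"]
        for _, r in sham_rows.iterrows():
            mask = (
                (sham_as_active["participant_id"] == r["participant_id"])
                & (sham_as_active["tms_time"] == r["tms_time"])
                & (sham_as_active["tms_mode"] == "active")
            )
            sham_as_active.loc[mask, "value"] = r["value"]
        out = sham_normalize(sham_as_active)
        assert np.allclose(out["delta"], 0.0)

    def test_undefined_member_propagates(self):
        cells = cells_frame([
            ("P1", "active", "BIP_only", "PcU", 0.6, 10, True),
            ("P1", "sham", "BIP_only", "PcU", math.nan, 0, False),
        ])
        out = sham_normalize(cells)
        assert not out.loc[0, "defined"]


class TestContrasts:
    def test_early_minus_late(self):
        delta = delta_frame({"P1": {"E30_BIP": -0.1, "E70_BIP": -0.1,
                                    "BIP_L150": 0.0, "BIP_L190": 0.0}})
        vec = early_late_contrast(delta, "PrC")
        assert vec.values["P1"] == pytest.approx(-0.1)
        assert vec.provenance["sign"] == "early_minus_late"

    def test_all_equal_gives_zero(self):
        delta = delta_frame({"P1": {t: -0.3 for t in
                                    ("E30_BIP", "E70_BIP", "BIP_L150", "BIP_L190")}})
        assert early_late_contrast(delta, "PrC").values["P1"] == pytest.approx(0.0)

    def test_undefined_member_averages_rest(self):
        delta = delta_frame({"P1": {"E30_BIP": math.nan, "E70_BIP": -0.2,
                                    "BIP_L150": 0.0, "BIP_L190": 0.0}})
        vec = early_late_contrast(delta, "PrC")
        assert vec.values["P1"] == pytest.approx(-0.2)

    def test_strict_mode_drops_participant(self):
        delta = delta_frame({"P1": {"E30_BIP": math.nan, "E70_BIP": -0.2,
                                    "BIP_L150": 0.0, "BIP_L190": 0.0},
                             "P2": {"E30_BIP": -0.1, "E70_BIP": -0.1,
                                    "BIP_L150": 0.0, "BIP_L190": 0.0}})
        vec = early_late_contrast(delta, "PrC", strict=True)
        assert list(vec.values.index) == ["P2"]
        assert "P1" in vec.provenance["dropped_undefined"]

    def test_fine_contrast_identical_times_zero(self):
        delta = delta_frame({"P1": {"E30_BIP": -0.4}})
        vec = fine_contrast(delta, "PrC", "E30_BIP", "E30_BIP")
        assert vec.values["P1"] == 0.0

    def test_fine_contrast_difference(self):
        delta = delta_frame({"P1": {"E30_BIP": -0.4, "BIP_L190": -0.1}})
        vec = fine_contrast(delta, "PrC", "E30_BIP", "BIP_L190")
        assert vec.values["P1"] == pytest.approx(-0.3)


class TestTTests:
    def test_hand_computed_example(self):
        x = [2.0, 4.0, 6.0, 8.0]  # mean 5, sd ~2.582
        res = one_sample_t(x)
        sd = np.std(x, ddof=1)
        assert res.t == pytest.approx(5.0 / (sd / 2.0))
        assert res.mean == 5.0 and res.df == 3
        assert res.cohens_d == pytest.approx(5.0 / sd)
        assert res.ci95[0] < 5.0 < res.ci95[1]

    def test_symmetric_zero_mean(self):
        res = one_sample_t([-1.0, 1.0, -2.0, 2.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        res = one_sample_t([0.4, 0.4, 0.4])
        assert res.degenerate and math.isinf(res.t)

    def test_paired_equals_one_sample_of_differences(self, rng):
        a = pd.Series(rng.normal(0.1, 1, 30))
        b = pd.Series(rng.normal(0.0, 1, 30))
        pt = paired_t(a, b)
        ost = one_sample_t(a - b)
        assert pt == ost  # exact: same code path by construction

    def test_paired_shift_by_constant(self, rng):
        a = pd.Series(rng.normal(0, 1, 20))
        res = paired_t(a + 0.7, a)
        assert res.mean == pytest.approx(0.7)
        assert res.degenerate  # zero-variance differences

    def test_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0.2, 1, 25)
        res = one_sample_t(x)
        ref = stats.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestWithinSubjectSE:
    def test_pure_subject_offsets_give_zero(self):
        rows = []
        for i, offset in enumerate([0.0, 0.3, -0.2, 0.5]):
            for mode in TMS_MODES:
                for t in TMS_TIMES:
                    rows.append((f"P{i}", mode, t, "PrC", 0.5 + offset, 10, True))
        se = within_subject_se(cells_frame(rows), "PrC")
        assert np.allclose(se, 0.0)

    def test_single_condition_undefined(self):
        rows = [("P1", "sham", "BIP_only", "PrC", 0.5, 10, True),
                ("P2", "sham", "BIP_only", "PrC", 0.6, 10, True)]
        se = within_subject_se(cells_frame(rows), "PrC")
        assert se.isna().all()

    def test_matches_bruteforce_centering(self, rng):
        rows = []
        data = {}
        for i in range(8):
            offset = rng.normal(0, 0.3)
            for mode in TMS_MODES:
                for t in TMS_TIMES:
                    v = 0.5 + offset + rng.normal(0, 0.05)
                    rows.append((f"P{i}", mode, t, "PrC", v, 10, True))
                    data[(i, mode, t)] = v
        se = within_subject_se(cells_frame(rows), "PrC")
        # brute force: explicit loops, aligned to the returned condition order
        conds = list(se.index)
        mat = np.array([[data[(i, m, t)] for (m, t) in conds] for i in range(8)])
        centered = mat - mat.mean(axis=1, keepdims=True) + mat.mean()
        k = mat.shape[1]
        expect = centered.std(axis=0, ddof=1) / np.sqrt(8) * np.sqrt(k / (k - 1))
        assert np.allclose(np.asarray(se), expect)


@pytest.fixture(scope="module")
def bundle(small_cohort):
    cfg = AnalysisConfig(measures=("PrC", "PcU", "BrC"), compute_bayes=False)
    return run_report(small_cohort, cfg)


class TestRunReport:
    def test_row_census(self, bundle):
        assert list(bundle.report["measure"]) == ["PrC", "PcU", "BrC"]

    def test_full_report_has_eight_measure_rows(self, small_cohort):
        cfg = AnalysisConfig(compute_bayes=False)
        bundle = run_report(small_cohort, cfg)
        assert list(bundle.report["measure"]) == [
            "PcU", "PrC", "PCm", "BrC", "PrA", "BrA", "PrS", "BrS"]

    def test_deterministic_rerun(self, small_cohort, bundle):
        cfg = AnalysisConfig(measures=("PrC", "PcU", "BrC"), compute_bayes=False)
        again = run_report(small_cohort, cfg)
        pd.testing.assert_frame_equal(bundle.report, again.report)
        pd.testing.assert_frame_equal(bundle.exclusions, again.exclusions)

    def test_double_baseline_identity(self, small_cohort):
        """The early-vs-late t-test equals a paired t-test of the early and
        late delta vectors, to machine precision."""
        cells = measure_table(small_cohort, ["PrC"])
        delta = sham_normalize(cells)
        early = delta[delta["tms_time"].isin(["E30_BIP", "E70_BIP"])].groupby(
            "participant_id")["delta"].mean()
        late = delta[delta["tms_time"].isin(["BIP_L150", "BIP_L190"])].groupby(
            "participant_id")["delta"].mean()
        direct = one_sample_t(early_late_contrast(delta, "PrC").values)
        via_pair = paired_t(early, late)
        assert via_pair.t == pytest.approx(direct.t, rel=1e-12)
        assert via_pair.mean == pytest.approx(direct.mean, rel=1e-12)

    def test_chance_rule_scope_containment(self, small_cohort, bundle):
        """PcU-only exclusions never touch the PrC/BrC analyses."""
        chance_excluded = set(
            bundle.exclusions.query("rule == 'chance_pcu' and excluded")[
                "participant_id"]
        )
        prc_vec = bundle.vectors["PrC early_vs_late"]
        if chance_excluded:
            assert chance_excluded <= set(prc_vec.values.index)
        pcu_vec = bundle.vectors["PcU early_vs_late"]
        assert not (chance_excluded & set(pcu_vec.values.index))

    def test_chauvenet_scope_is_per_vector(self, bundle):
        """A vector-point outlier removal leaves other vectors' n intact."""
        ns = bundle.report.set_index("measure")["n"]
        outliers = bundle.report.set_index("measure")["n_outliers"]
        base_n = len({p for v in bundle.vectors.values() for p in v.values.index}
                     | {p for v in bundle.vectors.values() for p in v.excluded_outliers})
        for m in ("PrC", "BrC"):
            assert ns[m] + outliers[m] <= base_n

    def test_exclusion_report_written(self, tmp_path, bundle):
        bundle.write(tmp_path)
        assert (tmp_path / "report.csv").exists()
        assert (tmp_path / "exclusions.csv").exists()
        assert (tmp_path / "run.log").read_text().strip()

    def test_config_rejects_unknown_keys(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("alpha: 0.05\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            AnalysisConfig.from_file(p)
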