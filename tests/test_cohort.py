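import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silacturnover import cohort


def _values(by_subject, value_col="half_life_h", protein="P1"):
    """by_subject: {(subject, group): value} for one protein."""
    rows = [
        {"protein_id": protein, "subject_id": s, "group": g, value_col: v}
        for (s, g), v in by_subject.items()
    ]
    return pd.DataFrame(rows)


def _two_groups(a_vals, b_vals, protein="P1", value_col="half_life_h"):
    by = {(f"D{i}", cohort.GROUP_A): v for i, v in enumerate(a_vals)}
    by |= {(f"N{i}", cohort.GROUP_B): v for i, v in enumerate(b_vals)}
    return _values(by, value_col=value_col, protein=protein)


class TestSummarize:
    def test_single_subject_excluded(self):
        vals = _values({("D1", cohort.GROUP_A): 20.0})
        out = cohort.summarize_protein(vals, "half_life_h")
        assert len(out) == 0

    def test_mean_of_two_subjects(self):
        vals = _values(
            {("D1", cohort.GROUP_A): 20.0, ("D2", cohort.GROUP_A): 30.0}
        )
        out = cohort.summarize_protein(vals, "half_life_h")
        assert out.loc[0, "mean"] == pytest.approx(25.0)

    def test_equal_values_have_zero_sd(self):
        vals = _values(
            {(f"D{i}", cohort.GROUP_A): 42.0 for i in range(10)}
        )
        out = cohort.summarize_protein(vals, "half_life_h")
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n_subjects"] == 10


class TestCompareGroups:
    def test_identical_groups_give_p_one_and_unit_fold_change(self):
        df = _two_groups([10, 10, 10], [10, 10, 10], value_col="mean_abundance")
        out = cohort.compare_groups(df, "mean_abundance", "abundance")
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        """Oracle: explicit pooled-variance t statistic and CDF evaluation."""
        a, b = np.array([10.0, 11.0, 12.0]), np.array([20.0, 21.0, 22.0])
        df = _two_groups(a, b)
        out = cohort.compare_groups(df, "half_life_h", "half_life")
        sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_oracle = 2 * stats.t.sf(abs(t), df=4)
        assert out.loc[0, "p_value"] == pytest.approx(p_oracle, rel=1e-12)

    def test_insufficient_subjects_skipped_with_reason(self):
        df = _two_groups([10.0], [20, 21, 22, 23, 24])
        out = cohort.compare_groups(df, "half_life_h", "half_life")
        assert np.isnan(out.loc[0, "p_value"])
        assert out.loc[0, "skipped"] == "insufficient subjects"

    @pytest.mark.parametrize(
        "a, b, expected_fc",
        [
            ([1.0, 1.0], [2.0, 2.0], 2.0),    # higher in nephropathic
            ([2.0, 2.0], [1.0, 1.0], -2.0),   # lower -> negative reciprocal
        ],
    )
    def test_signed_fold_change_convention(self, a, b, expected_fc):
        df = _two_groups(a, b, value_col="mean_abundance")
        out = cohort.compare_groups(df, "mean_abundance", "abundance")
        assert out.loc[0, "fold_change"] == pytest.approx(expected_fc)
        assert abs(out.loc[0, "fold_change"]) >= 1.0

    def test_bh_adjusted_monotone_in_raw_p(self, rng):
        frames = [
            _two_groups(
                rng.normal(30, 3, 5), rng.normal(30 + i, 3, 5), protein=f"P{i:03d}"
            )
            for i in range(40)
        ]
        out = cohort.compare_groups(
            pd.concat(frames), "half_life_h", "half_life"
        )
        out = out.sort_values("p_value")
        assert (out["fdr_bh"].diff().dropna() >= -1e-12).all()
        assert (out["fdr_bh"] >= out["p_value"] - 1e-12).all()

    def test_zero_pooled_variance_with_unequal_means(self):
        df = _two_groups([5.0, 5.0], [9.0, 9.0])
        out = cohort.compare_groups(df, "half_life_h", "half_life")
        assert out.loc[0, "p_value"] > 0
        assert out.loc[0, "p_value"] < 1e-300
        assert out.loc[0, "skipped"] == "zero pooled variance"

    def test_normality_flag_present(self):
        df = _two_groups([10, 11, 12, 13, 14], [20, 21, 22, 23, 24])
        out = cohort.compare_groups(df, "half_life_h", "half_life")
        assert out.loc[0, "normality_ok"] in (True, False)


class TestBinning:
    @pytest.mark.parametrize(
        "halflife, label",
        [
            (15.0, "<20"),
            (59.9, "[50,60)"),
            (90.0, ">=90"),   # left-closed upper bin
            (20.0, "[20,30)"),
        ],
    )
    def test_halflife_interval_labels(self, halflife, label):
        summary = pd.DataFrame(
            {"protein_id": ["P1"], "mean": [halflife], "sd": [1.0], "n_subjects": [5]}
        )
        binned, _ = cohort.bin_by_halflife(summary)
        assert binned.loc[0, "halflife_bin"] == label

    @pytest.mark.parametrize(
        "log2, label", [(9.5, ">=9"), (7.25, "[7,7.5)"), (4.0, "<5")]
    )
    def test_abundance_interval_labels(self, log2, label):
        summary = pd.DataFrame({"protein_id": ["P1"], "mean_log2": [log2]})
        binned, _ = cohort.bin_by_abundance(summary)
        assert binned.loc[0, "abundance_bin"] == label

    def test_counts_partition_binned_proteins(self, rng):
        summary = pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(200)],
                "mean": rng.uniform(1.0, 150.0, 200),
                "sd": 1.0,
                "n_subjects": 5,
            }
        )
        _, counts = cohort.bin_by_halflife(summary)
        assert counts["n_proteins"].sum() == 200
        assert len(counts) == 9

    def test_nonpositive_halflife_excluded(self):
        summary = pd.DataFrame(
            {"protein_id": ["P1", "P2"], "mean": [-5.0, 30.0], "sd": 1.0,
             "n_subjects": 5}
        )
        binned, counts = cohort.bin_by_halflife(summary)
        assert binned.loc[0, "halflife_bin"] == "excluded_nonpositive"
        assert counts["n_proteins"].sum() == 1


class TestQuadrants:
    TABLE = pd.DataFrame(
        {
            "protein_id": ["slow_big", "fast_big", "fast_small", "slow_small", "at_thr"],
            "mean_k": [0.005, 0.05, 0.05, 0.005, 0.01],
            "mean_abundance": [1e-2, 1e-2, 1e-4, 1e-4, 1e-3],
        }
    )

    def test_labels_and_tie_rule(self):
        out = cohort.quadrant_classify(self.TABLE, 0.01, 1e-3)
        got = dict(zip(out["protein_id"], out["quadrant"]))
        assert got["slow_big"] == "low-k/high-A"    # stable and abundant
        assert got["fast_big"] == "high-k/high-A"
        assert got["fast_small"] == "high-k/low-A"
        assert got["slow_small"] == "low-k/low-A"
        assert got["at_thr"] == "high-k/high-A"     # thresholds close upward

    def test_counts_partition(self):
        out = cohort.quadrant_classify(self.TABLE, 0.01, 1e-3)
        assert out["quadrant"].value_counts().sum() == len(self.TABLE)

    def test_missing_coordinate_unclassified(self):
        table = self.TABLE.copy()
        table.loc[0, "mean_k"] = np.nan
        out = cohort.quadrant_classify(table, 0.01, 1e-3)
        assert out.loc[0, "quadrant"] == "unclassified"


class TestComplexVsRandom:
    def _summary(self, rng, n=100):
        return pd.DataFrame(
            {
                "protein_id": [f"P{i:03d}" for i in range(n)],
                "mean": rng.uniform(10, 200, n),
                "sd": 1.0,
                "n_subjects": 5,
            }
        )

    def test_identical_member_halflives_beat_every_random_set(self, rng):
        summary = self._summary(rng)
        members = ["P000", "P001", "P002", "P003"]
        summary.loc[summary["protein_id"].isin(members), "mean"] = 55.0
        report = cohort.complex_vs_random(members, summary, seed=3)
        assert report["complex_sd"] == 0.0
        assert report["frac_random_sd_larger"] == 1.0

    def test_random_subset_fraction_is_null_calibrated(self, rng):
        """A 'complex' drawn at random is not systematically tighter."""
        summary = self._summary(rng, n=300)
        fracs = [
            cohort.complex_vs_random(
                list(rng.choice(summary["protein_id"], 8, replace=False)),
                summary, seed=int(seed),
            )["frac_random_sd_larger"]
            for seed in range(40)
        ]
        assert 0.25 < np.mean(fracs) < 0.75

    def test_same_seed_reproduces_populations(self, rng):
        summary = self._summary(rng)
        r1 = cohort.complex_vs_random(["P000", "P001", "P002"], summary, seed=11)
        r2 = cohort.complex_vs_random(["P000", "P001", "P002"], summary, seed=11)
        pd.testing.assert_frame_equal(r1["populations"], r2["populations"])

    def test_missing_members_error_lists_ids(self, rng):
        summary = self._summary(rng, n=10)
        with pytest.raises(ValueError, match="PX99"):
            cohort.complex_vs_random(["P000", "P001", "PX99"], summary)
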