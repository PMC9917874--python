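import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silacturnover import noise


def _bins_from_model(alpha, beta, r_mids, n=50):
    """Exact bin table generated from a known SD-versus-ratio model."""
    r = np.asarray(r_mids, dtype=float)
    sd = np.sqrt(alpha**2 + beta**2 * r**2)
    return pd.DataFrame(
        {
            "r_lo": r - 0.025,
            "r_hi": r + 0.025,
            "r_mid": r,
            "n": n,
            "median_sd": sd,
            "median_cv": 100 * sd / np.maximum(r, 1e-9),
            "underfilled": False,
        }
    )


def _ratio_table(r, sd, cv):
    return pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(len(r))],
            "subject_id": "S1",
            "group": "control_diabetic",
            "time_h": 4.0,
            "r": r,
            "n_peptides": 3,
            "sd_peptides": sd,
            "cv_peptides": cv,
            "single_peptide": False,
        }
    )


class TestPredictSd:
    def test_sd_at_zero_ratio_is_alpha(self):
        assert noise.NoiseModel(0.02, 0.1).predict_sd(0.0) == 0.02

    def test_sd_at_unit_ratio(self):
        got = noise.NoiseModel(0.02, 0.1).predict_sd(1.0)
        assert got == pytest.approx(np.sqrt(0.0004 + 0.01))  # ~0.10198

    def test_cv_asymptote_is_beta(self):
        model = noise.NoiseModel(0.02, 0.1)
        assert model.predict_sd(1e6) / 1e6 == pytest.approx(0.1, rel=1e-6)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            noise.NoiseModel(0.02, 0.1).predict_sd(-0.1)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            noise.NoiseModel(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        alpha=st.floats(1e-4, 1.0),
        beta=st.floats(0.0, 1.0),
        r=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=20),
    )
    def test_sd_monotone_nondecreasing_in_r(self, alpha, beta, r):
        model = noise.NoiseModel(alpha, beta)
        sd = model.predict_sd(np.sort(np.asarray(r)))
        assert np.all(np.diff(sd) >= -1e-15)


class TestBinRatios:
    def test_uniform_measurements_fill_equal_bins(self):
        r = np.linspace(0.0, 0.1499, 30)
        bins = noise.bin_ratios(_ratio_table(r, 0.01, 10.0))
        assert len(bins) == 3
        assert list(bins["n"]) == [10, 10, 10]

    def test_sparse_tail_merges_rightward(self):
        r = np.concatenate([np.linspace(0.0, 0.049, 12), [0.06, 0.07, 0.08]])
        bins = noise.bin_ratios(_ratio_table(r, 0.01, 10.0))
        assert len(bins) == 2
        assert bins.loc[0, "n"] == 12
        assert bins.loc[1, "n"] == 3
        assert bool(bins.loc[1, "underfilled"])

    def test_bin_records_median_sd(self):
        r = np.full(10, 0.02)
        sds = np.array([0.01, 0.02, 0.03] * 3 + [0.02])
        bins = noise.bin_ratios(_ratio_table(r, sds, 10.0))
        assert bins.loc[0, "median_sd"] == pytest.approx(0.02)

    def test_single_peptide_entries_ignored(self):
        table = _ratio_table(np.linspace(0, 0.14, 30), 0.01, 10.0)
        table.loc[:, "n_peptides"] = 1
        with pytest.raises(ValueError):
            noise.bin_ratios(table)

    def test_bins_tile_without_overlap(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(0, 1.2, 300)
        bins = noise.bin_ratios(_ratio_table(r, 0.02, 10.0))
        assert (bins["r_lo"].to_numpy()[1:] == bins["r_hi"].to_numpy()[:-1]).all()
        assert bins["n"].sum() == 300


class TestFitNoiseModel:
    def test_exact_recovery_from_noiseless_bins(self):
        bins = _bins_from_model(0.02, 0.1, np.arange(0.025, 1.0, 0.05))
        model, diag = noise.fit_noise_model(bins)
        assert model.alpha == pytest.approx(0.02, abs=1e-6)
        assert model.beta == pytest.approx(0.1, abs=1e-6)
        assert diag["residual_norm"] < 1e-8

    def test_constant_sd_near_origin_gives_alpha(self):
        # all bins at r ~ 0 with the same SD: the floor absorbs everything
        bins = _bins_from_model(0.0, 0.0, np.linspace(1e-4, 5e-4, 5))
        bins["median_sd"] = 0.03
        model, _ = noise.fit_noise_model(bins)
        assert model.alpha == pytest.approx(0.03, abs=1e-5)
        assert model.beta == pytest.approx(0.0, abs=0.2)  # unidentified scale

    def test_too_few_bins_errors(self):
        bins = _bins_from_model(0.02, 0.1, [0.1, 0.2])
        with pytest.raises(ValueError):
            noise.fit_noise_model(bins)

    def test_matches_grid_search_oracle(self, rng):
        """Brute-force grid over (alpha, beta) finds the same minimiser."""
        for _ in range(5):
            r_mid = np.sort(rng.uniform(0.02, 1.0, 8))
            true_a, true_b = rng.uniform(0.005, 0.08), rng.uniform(0.02, 0.4)
            sd = np.sqrt(true_a**2 + true_b**2 * r_mid**2)
            sd *= 1 + rng.normal(0, 0.05, sd.size)  # perturb the bin medians
            bins = _bins_from_model(0, 0, r_mid)
            bins["median_sd"] = sd
            model, _ = noise.fit_noise_model(bins)

            a_grid = np.arange(0.0, 0.1 + 1e-9, 1e-4)
            b_grid = np.arange(0.0, 0.5 + 1e-9, 1e-4)
            best = (np.inf, None, None)
            for b_chunk in np.array_split(b_grid, 50):
                sse = (
                    (
                        sd[None, None, :]
                        - np.sqrt(
                            a_grid[:, None, None] ** 2
                            + b_chunk[None, :, None] ** 2 * r_mid[None, None, :] ** 2
                        )
                    )
                    ** 2
                ).sum(axis=2)
                i, j = np.unravel_index(np.argmin(sse), sse.shape)
                if sse[i, j] < best[0]:
                    best = (sse[i, j], a_grid[i], b_chunk[j])
            assert model.alpha == pytest.approx(best[1], abs=2e-4)
            assert model.beta == pytest.approx(best[2], abs=2e-4)

    def test_scale_consistency(self):
        """Scaling r and SD by c scales alpha by c and leaves beta fixed."""
        r_mid = np.arange(0.025, 0.6, 0.05)
        bins = _bins_from_model(0.02, 0.1, r_mid)
        model1, _ = noise.fit_noise_model(bins)
        c = 3.0
        scaled = bins.copy()
        for col in ("r_lo", "r_hi", "r_mid", "median_sd"):
            scaled[col] = scaled[col] * c
        model2, _ = noise.fit_noise_model(scaled)
        assert model2.alpha == pytest.approx(c * model1.alpha, rel=1e-4)
        assert model2.beta == pytest.approx(model1.beta, rel=1e-4)


class TestConstantModelDiagnostic:
    def test_mixed_model_rejects_both_constants(self):
        bins = _bins_from_model(0.02, 0.1, np.arange(0.025, 1.0, 0.05))
        report = noise.constant_model_diagnostic(bins)
        assert report["sd_trend"] > 0 and report["reject_constant_sd"]
        assert report["cv_trend"] < 0 and report["reject_constant_cv"]
        assert report["verdict"] == "reject_constant_sd_and_constant_cv"

    def test_constant_sd_not_rejected(self):
        bins = _bins_from_model(0.02, 0.0, np.arange(0.025, 1.0, 0.05))
        report = noise.constant_model_diagnostic(bins)
        assert not report["reject_constant_sd"]

    def test_pure_proportional_noise_keeps_constant_cv(self):
        bins = _bins_from_model(0.0, 0.1, np.arange(0.025, 1.0, 0.05))
        bins["median_cv"] = 10.0  # CV exactly flat
        report = noise.constant_model_diagnostic(bins)
        assert not report["reject_constant_cv"]


def test_model_file_round_trip(tmp_path):
    model = noise.NoiseModel(0.0213, 0.0974, source="fitted")
    path = tmp_path / "nm.txt"
    noise.save_noise_model(model, path)
    back = noise.load_noise_model(path)
    assert back.alpha == model.alpha
    assert back.beta == model.beta
    assert back.source == "fitted"
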