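import itertools

import numpy as np
import pandas as pd
import pytest

from nilgenetics.simulate import TrialDesign, py_truth, simulate_nil_trial
from nilgenetics.trial import (
    TRAITS,
    TrialRecord,
    VarianceComponents,
    blue_table,
    broad_sense_heritability,
    fit_blue,
    lsd_letters,
    lsd_threshold,
    pearson_matrix,
    records_to_frame,
)


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["environment", "plot", "plant", "genotype", "trait", "value"]
    )


class TestFitBlue:
    def test_balanced_two_env_toy(self):
        # genotype A env means 10, 20; genotype B env means 30, 40
        rows = []
        for env, (a, b) in zip(["E1", "E2"], [(10, 30), (20, 40)]):
            for geno, mean in [("A", a), ("B", b)]:
                for p in range(2):
                    rows.append((env, f"{env}{geno}{p}", "", geno, "FT", mean))
        blues, _ = fit_blue(_frame(rows), "FT")
        assert blues["A"] == pytest.approx(15.0, abs=1e-8)
        assert blues["B"] == pytest.approx(35.0, abs=1e-8)

    def test_zero_noise_blue_equals_class_mean(self):
        design = TrialDesign(
            plots_per_genotype_per_env=2, plants_per_plot=2,
            sigma2_env=0.0, sigma2_plot=0.0, sigma2_resid=0.0,
        )
        df = simulate_nil_trial({"PY": py_truth()}, design, seed=3)
        blues, vc = fit_blue(df, "PY")
        means = df.groupby("genotype")["value"].mean()
        assert np.max(np.abs(blues - means.loc[blues.index])) < 1e-8
        assert vc.sigma2_resid < 1e-8

    def test_balanced_equals_two_stage_means(self, small_trial):
        """BLUEs on balanced data equal the mean of environment means."""
        blues, _ = fit_blue(small_trial, "PY", estimate_genotype_variance=False)
        two_stage = (
            small_trial[small_trial["trait"] == "PY"]
            .groupby(["genotype", "environment"])["value"].mean()
            .groupby("genotype").mean()
        )
        assert np.max(np.abs(blues - two_stage.loc[blues.index])) < 1e-8

    def test_plot_level_trait_handled(self, small_trial):
        blues, vc = fit_blue(small_trial, "FT")
        assert vc.sigma2_resid == 0.0  # FT residual is the plot term
        assert vc.sigma2_plot > 0

    def test_single_environment_rejected(self):
        rows = [("E1", "p1", "", "A", "FT", 1.0), ("E1", "p2", "", "B", "FT", 2.0)]
        with pytest.raises(ValueError, match="2 environments"):
            fit_blue(_frame(rows), "FT")

    def test_unknown_trait_rejected(self):
        df = _frame([("E1", "p", "", "A", "FT", 1.0)])
        df.loc[0, "trait"] = "XYZ"
        with pytest.raises(ValueError, match="XYZ"):
            records_to_frame(df)

    def test_variance_components_near_truth_with_replication(self):
        # estimates approach the generating components as replication grows
        truth = {"PY": py_truth()}
        errs = []
        for plots, plants in [(2, 2), (6, 8)]:
            design = TrialDesign(
                plots_per_genotype_per_env=plots, plants_per_plot=plants,
                sigma2_env=1.0, sigma2_plot=2.0, sigma2_resid=3.0,
            )
            df = simulate_nil_trial(truth, design, seed=5)
            _, vc = fit_blue(df, "PY", estimate_genotype_variance=False)
            errs.append(abs(vc.sigma2_plot - 2.0) + abs(vc.sigma2_resid - 3.0))
        assert errs[1] < errs[0]
        assert errs[1] < 0.5

    def test_trial_record_validation(self):
        with pytest.raises(ValueError, match="unknown trait"):
            TrialRecord("E", "p", None, "A", "XYZ", 1.0)
        with pytest.raises(ValueError, match="non-finite"):
            TrialRecord("E", "p", None, "A", "FT", float("nan"))


class TestHeritability:
    def test_no_error_variance_gives_one(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, sigma2_geno=2.0)
        assert broad_sense_heritability(vc, 3, 2) == 1.0

    def test_direct_arithmetic(self):
        vc = VarianceComponents(0.0, 3.0, 6.0, sigma2_geno=4.0)
        assert broad_sense_heritability(vc, 3, 2) == pytest.approx(4 / 6, abs=1e-12)

    def test_all_zero_components_rejected(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, sigma2_geno=0.0)
        with pytest.raises(ValueError):
            broad_sense_heritability(vc, 3, 2)

    def test_simulated_high_heritability_trait(self):
        # components chosen so the entry-mean formula gives ~0.86
        design = TrialDesign(
            plots_per_genotype_per_env=5, plants_per_plot=1,
            sigma2_env=25.0, sigma2_plot=6.0, sigma2_resid=0.0,
        )
        truth = {"FT": py_truth(m=100.0)}  # sizeable genetic spread
        df = simulate_nil_trial(truth, design, seed=21)
        _, vc = fit_blue(df, "FT")
        h2 = broad_sense_heritability(vc, n_env=3, n_reps=5)
        assert 0.7 < h2 <= 1.0


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(5.0)
        table = pd.DataFrame({"FT": x, "PY": 2 * x + 1, "BN": [3, 1, 4, 1, 5]})
        corr = pearson_matrix(table)
        assert corr.loc["FT", "FT"] == 1.0
        assert corr.loc["FT", "PY"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_two_pass_oracle(self, blues_all_traits):
        corr = pearson_matrix(blues_all_traits)
        cols = list(blues_all_traits.columns)
        for t1, t2 in itertools.combinations(cols, 2):
            a = blues_all_traits[t1].to_numpy()
            b = blues_all_traits[t2].to_numpy()
            am, bm = a - a.mean(), b - b.mean()
            oracle = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert corr.loc[t1, t2] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_trait_flagged(self):
        table = pd.DataFrame({"FT": [1.0, 2.0, 3.0], "PY": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="PY"):
            corr = pearson_matrix(table)
        assert np.isnan(corr.loc["FT", "PY"])
        assert np.isnan(corr.loc["PY", "PY"])

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"FT": [1.0, 2.0]}))


class TestLSDLetters:
    def test_all_identical_means_share_a(self):
        letters = lsd_letters({"A": 5.0, "B": 5.0, "C": 5.0}, 1.0, 10, 4)
        assert set(letters.values()) == {"a"}

    def _letters_with_lsd(self, means, lsd):
        # choose mse so that the threshold equals the requested LSD (df large)
        import scipy.stats

        t = scipy.stats.t.ppf(0.975, 10_000)
        mse = (lsd / t) ** 2 / 2
        return lsd_letters(means, mse, 10_000, 1), lsd

    def test_all_separated(self):
        letters, _ = self._letters_with_lsd({"A": 1.0, "B": 10.0, "C": 20.0}, 2.0)
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_close_pair_shares_letter(self):
        letters, _ = self._letters_with_lsd({"A": 1.0, "B": 1.5, "C": 20.0}, 2.0)
        assert letters == {"A": "a", "B": "a", "C": "b"}

    @pytest.mark.parametrize(
        "env_means",
        [
            # published per-environment flowering-time means of the 8 NILs
            [65.6, 111.4, 113.0, 123.8, 133.0, 140.8, 143.6, 148.0],  # Jiangling
            [58.0, 89.8, 90.4, 102.2, 128.6, 137.2, 138.4, 140.6],    # Wuhan
            [50.2, 53.4, 54.2, 59.4, 59.8, 63.8, 66.6, 68.6],         # Minle
        ],
    )
    def test_letter_sequence_increases_with_flowering_time(self, env_means):
        means = {f"ID{i + 1:02d}": m for i, m in enumerate(env_means)}
        letters, _ = self._letters_with_lsd(means, 0.05)  # small enough LSD
        seq = [letters[f"ID{i + 1:02d}"] for i in range(8)]
        assert seq == sorted(seq)
        assert len(set(seq)) == 8  # strictly increasing at tiny LSD

    def test_pairwise_oracle(self, rng):
        """Two genotypes share a letter iff their means differ by < LSD."""
        for _ in range(20):
            means = {f"G{i}": float(v) for i, v in enumerate(rng.normal(0, 3, 10))}
            letters = lsd_letters(means, mse=2.0, df_error=30, n_per_mean=5)
            lsd = lsd_threshold(2.0, 30, 5)
            for g1, g2 in itertools.combinations(means, 2):
                shared = bool(set(letters[g1]) & set(letters[g2]))
                assert shared == (abs(means[g1] - means[g2]) < lsd), (g1, g2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lsd_threshold(-1.0, 10, 2)
        with pytest.raises(ValueError):
            lsd_threshold(1.0, 0, 2)
        with pytest.raises(ValueError):
            lsd_threshold(1.0, 10, 2, alpha=1.5)


def test_blue_table_multi_trait(small_trial):
    table = blue_table(small_trial, ["PY", "FT"], estimate_genotype_variance=False)
    assert list(table.columns) == ["PY", "FT"]
    assert table.shape == (27, 2)
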