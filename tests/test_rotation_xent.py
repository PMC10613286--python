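import numpy as np
import pandas as pd
import pytest

from glottolearn.compression_lm import CompressorConfig, register_backend
from glottolearn.corpus_io import ParallelCorpus
from glottolearn.lmm import indicator_matrix
from glottolearn.rotation_xent import (
    assign_folds,
    corpus_cross_entropies,
    cross_entropy_series,
    fit_slope_model,
    make_training_schedule,
)


def _grid_corpus(n_books=10, per_book=100, text="a b"):
    verses = {
        (f"b{b + 1:02d}", 1, v + 1): {"LX": text}
        for b in range(n_books)
        for v in range(per_book)
    }
    return ParallelCorpus(["LX"], verses)


class TestFoldAssignment:
    def test_balanced_stratified_counts(self):
        corpus = _grid_corpus(10, 100)
        a = assign_folds(corpus, 10, seed=0)
        counts = pd.Series(list(a.folds.values())).value_counts()
        assert (counts == 100).all()
        per_book = pd.DataFrame(
            [(k[0], f) for k, f in a.folds.items()], columns=["book", "fold"]
        ).groupby(["book", "fold"]).size()
        assert (per_book == 10).all()

    def test_partition_covers_all_verses(self):
        corpus = _grid_corpus(3, 30)
        a = assign_folds(corpus, 10, seed=1)
        assert set(a.folds) == set(corpus.verse_keys)

    def test_deterministic_given_seed(self):
        corpus = _grid_corpus(3, 30)
        assert assign_folds(corpus, 10, seed=5).folds == assign_folds(corpus, 10, seed=5).folds

    def test_small_book_raises(self):
        corpus = _grid_corpus(1, 5)
        with pytest.raises(ValueError):
            assign_folds(corpus, 10, seed=0)


class TestTrainingSchedule:
    def test_ten_permutations_of_length_nine(self):
        a = assign_folds(_grid_corpus(2, 20), 10, seed=0)
        s = make_training_schedule(a, seed=0)
        assert len(s.order) == 10
        for test_fold, perm in s.order.items():
            assert len(perm) == 9
            assert test_fold not in perm
            assert sorted(perm) == [f for f in range(1, 11) if f != test_fold]

    def test_reproducible(self):
        a = assign_folds(_grid_corpus(2, 20), 10, seed=0)
        assert make_training_schedule(a, 3).order == make_training_schedule(a, 3).order


class TestCrossEntropySeries:
    def test_degenerate_backend_gives_constant_H(self):
        # a backend charging 8 bits/byte makes H_f the byte length of the
        # coded test fold per verse, constant in f (identical verse text
        # keeps the symbol tables byte-identical across prefixes)
        register_backend("bytelen", lambda b: 8.0 * len(b))
        corpus = _grid_corpus(2, 20, text="a b")
        a = assign_folds(corpus, 10, seed=0)
        s = make_training_schedule(a, seed=0)
        cfg = CompressorConfig(backend="bytelen")
        xe = cross_entropy_series(corpus, "LX", a, s, cfg, "word", n_test_folds=2)
        n_v = len(a.keys_in_fold(1))
        expected = 8.0 * 4 * (2 * n_v) / n_v  # two 4-byte symbols per verse
        assert np.allclose(xe["H"], expected)

    def test_full_design_yields_90_records(self, single_language_corpus):
        corpus, _ = single_language_corpus
        a = assign_folds(corpus, 10, seed=1)
        s = make_training_schedule(a, seed=2)
        xe = cross_entropy_series(corpus, "LX", a, s, CompressorConfig(order=2), "word")
        assert len(xe) == 90
        assert sorted(xe["f"].unique()) == list(range(1, 10))
        assert sorted(xe["test_fold"].unique()) == list(range(1, 11))

    def test_learning_signal_is_strongly_negative_loglog(self, single_language_corpus):
        corpus, _ = single_language_corpus
        a = assign_folds(corpus, 10, seed=1)
        s = make_training_schedule(a, seed=2)
        xe = cross_entropy_series(corpus, "LX", a, s, CompressorConfig(order=2), "word")
        r = np.corrcoef(np.log(xe["H"]), np.log(xe["f"]))[0, 1]
        assert r <= -0.8

    def test_median_H_decreases_in_f(self, single_language_corpus):
        corpus, _ = single_language_corpus
        a = assign_folds(corpus, 10, seed=1)
        s = make_training_schedule(a, seed=2)
        xe = cross_entropy_series(corpus, "LX", a, s, CompressorConfig(order=2), "word")
        med = xe.groupby("f")["H"].median()
        diffs = np.diff(med.to_numpy())
        # decreasing in all but at most one sampling-noise step, and the
        # overall drop dominates any local wiggle
        assert (diffs < 0).sum() >= len(diffs) - 1
        assert med.iloc[-1] < med.iloc[0]

    def test_bpe_level_runs_and_learns_merges_from_training_only(self):
        corpus = _grid_corpus(2, 20, text="low lower lowest")
        a = assign_folds(corpus, 10, seed=0)
        s = make_training_schedule(a, seed=0)
        xe = cross_entropy_series(
            corpus, "LX", a, s, CompressorConfig(order=1), "bpe", n_test_folds=1
        )
        assert len(xe) == 9
        assert (xe["H"] > 0).all()


class TestSlopeModel:
    def _simulate(self, seed=0, n_lang=50, n_folds=10):
        rng = np.random.default_rng(seed)
        mu_true = rng.normal(0, 0.08, n_lang)
        intercepts = rng.normal(0, 0.3, n_lang)
        fold_eff = rng.normal(0, 0.05, n_folds)
        rows = []
        for i in range(n_lang):
            for tf in range(n_folds):
                for f in range(1, 10):
                    logH = (
                        3.0
                        - 0.3 * np.log(f)
                        + intercepts[i]
                        + mu_true[i] * np.log(f)
                        + fold_eff[tf]
                        + 0.05 * rng.standard_normal()
                    )
                    rows.append(
                        {"language": f"L{i:03d}", "test_fold": tf + 1, "f": f, "H": np.exp(logH)}
                    )
        return pd.DataFrame(rows), mu_true

    def test_recovers_known_slopes(self):
        df, mu_true = self._simulate()
        fit = fit_slope_model(df)
        assert np.corrcoef(fit.mu.to_numpy(), mu_true)[0, 1] > 0.9

    def test_blups_shrink_toward_zero(self):
        df, _ = self._simulate(seed=1)
        fit_het = fit_slope_model(df)
        # identical languages: remove heterogeneity, refit
        rng = np.random.default_rng(2)
        df_null = df.copy()
        df_null["H"] = np.exp(
            3.0 - 0.3 * np.log(df_null["f"]) + 0.05 * rng.standard_normal(len(df_null))
        )
        fit_null = fit_slope_model(df_null)
        assert fit_null.mu.abs().max() < fit_het.mu.abs().max()
        assert abs(fit_null.mu.mean()) < 1e-6

    def test_blup_mean_is_zero(self):
        df, _ = self._simulate(seed=3)
        fit = fit_slope_model(df)
        assert abs(fit.mu.mean()) < 1e-6

    def test_difficulty_orientation_on_synthetic_world(self, small_world):
        import scipy.stats as st

        a = assign_folds(small_world.corpus, 10, seed=1)
        s = make_training_schedule(a, seed=2)
        xe = corpus_cross_entropies(
            small_world.corpus, a, s, CompressorConfig(order=2), "word", n_test_folds=3
        )
        fit = fit_slope_model(xe)
        rho = st.spearmanr(
            fit.mu[small_world.truth.index], small_world.truth["d_true"]
        ).statistic
        assert rho <= -0.6
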