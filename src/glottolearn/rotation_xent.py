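"""Fold-rotation cross-entropy estimation of learning difficulty.

Verses are stratified by book into ten folds, identical across languages.
For each test fold a random training schedule (a permutation of the nine
remaining folds, shared across languages) is drawn; as folds are added one
by one the incremental cross entropy

    H_f = (R(T_f T_test) - R(T_f)) / N_v

is recorded, where ``R`` is the compressed size in bits (including the
compressed symbol-table serialization), ``T_f`` the concatenation of the
first ``f`` scheduled folds, ``T_test`` the test fold and ``N_v`` the
number of test verses.  ``H_f`` is therefore the average number of bits
needed to encode/predict a test verse after ``f`` folds of training.

A mixed-effects model of ``log H_f`` on ``log f`` — crossed random
intercepts for language and test fold, plus a per-language random slope
with unstructured intercept-slope covariance, fitted by REML — yields
per-language best linear unbiased predictions (BLUPs) ``mu`` of the slope
deviation.  Higher ``mu`` = flatter individual slope relative to the
population = faster learning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glottolearn.compression_lm import CompressorConfig, PPMModel, backend_codelength
from glottolearn.corpus_io import (
    BPEModel,
    ParallelCorpus,
    SymbolSequence,
    SymbolTable,
    VerseKey,
    encode_symbols,
    learn_bpe,
    tokenize,
)
from glottolearn.lmm import (
    IIDComponent,
    MixedLMResult,
    PairedComponent,
    fit_mixed_model,
    indicator_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Verse-key -> fold partition, stratified by book, shared across languages."""

    folds: dict[VerseKey, int]
    n_folds: int

    def keys_in_fold(self, fold: int) -> list[VerseKey]:
        return [k for k, f in sorted(self.folds.items()) if f == fold]


@dataclass
class TrainingSchedule:
    """Per test fold: the ordered permutation of the remaining folds."""

    order: dict[int, list[int]]


@dataclass
class SlopeModelFit:
    """REML slope-model summary with per-language difficulty BLUPs mu."""

    fixed_intercept: float
    fixed_slope: float
    mu: pd.Series  # per-language BLUP of the log-f random slope
    sigma2_mu: float
    varcomps: dict
    result: MixedLMResult


def assign_folds(corpus: ParallelCorpus, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly assign each verse of each book to one of ``n_folds`` folds.

    Stratification keeps per-book fold sizes within one of each other; the
    assignment is a deterministic function of the seed and is shared across
    languages (verse keys are language independent).
    """
    rng = np.random.default_rng(seed)
    folds: dict[VerseKey, int] = {}
    for book in corpus.books:
        keys = [k for k in corpus.verse_keys if k[0] == book]
        if len(keys) < n_folds:
            raise ValueError(f"book {book!r} has {len(keys)} verses < {n_folds} folds")
        perm = rng.permutation(len(keys))
        for slot, key_idx in enumerate(perm):
            folds[keys[key_idx]] = slot % n_folds + 1
    return FoldAssignment(folds=folds, n_folds=n_folds)


def make_training_schedule(assignment: FoldAssignment, seed: int = 0) -> TrainingSchedule:
    """One uniformly random permutation of the non-test folds per test fold."""
    rng = np.random.default_rng(seed)
    order = {}
    for test_fold in range(1, assignment.n_folds + 1):
        rest = [f for f in range(1, assignment.n_folds + 1) if f != test_fold]
        order[test_fold] = [rest[i] for i in rng.permutation(len(rest))]
    return TrainingSchedule(order=order)


def _fold_texts(
    corpus: ParallelCorpus, language: str, assignment: FoldAssignment
) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {f: [] for f in range(1, assignment.n_folds + 1)}
    for key in corpus.verse_keys:  # verse-key order, identical across languages
        out[assignment.folds[key]].append(corpus.verses[key][language])
    return out


def _coded_ids(symbols: list[str], vocab: dict[str, int]) -> np.ndarray:
    ids = np.empty(len(symbols), dtype=np.int64)
    for i, s in enumerate(symbols):
        ids[i] = vocab.setdefault(s, len(vocab))
    return ids


def _R_ppm(bits_stream: float, table: SymbolTable) -> float:
    return bits_stream + table.serialized_bits()


def cross_entropy_series(
    corpus: ParallelCorpus,
    language: str,
    assignment: FoldAssignment,
    schedule: TrainingSchedule,
    config: CompressorConfig | None = None,
    level: str = "word",
    n_test_folds: int | None = None,
) -> pd.DataFrame:
    """Incremental cross entropies for one language.

    Returns a tidy frame with columns ``language, level, backend, test_fold,
    f, H`` — ``n_test_folds * (n_folds - 1)`` records (90 for the full
    tenfold design).  Negative ``H`` records (possible with real byte-level
    backends on tiny inputs) are dropped with a warning.

    For the BPE level the merge rules are learned from the training folds
    ``T_f`` only, then applied to both training and test text.
    """
    config = config or CompressorConfig()
    n_folds = assignment.n_folds
    n_test_folds = n_test_folds or n_folds
    fold_verses = _fold_texts(corpus, language, assignment)
    if config.backend == "ppm" and level != "bpe":
        return _series_ppm_incremental(
            fold_verses, language, schedule, config, level, n_folds, n_test_folds
        )
    rows = []
    for test_fold in range(1, n_test_folds + 1):
        train_order = schedule.order[test_fold]
        test_verses = fold_verses[test_fold]
        n_v = len(test_verses)
        test_text = " ".join(test_verses)
        for f in range(1, n_folds):
            train_verses: list[str] = []
            for fold in train_order[:f]:
                train_verses.extend(fold_verses[fold])
            train_text = " ".join(train_verses)
            if level == "bpe":
                bpe = learn_bpe(train_verses)
                train_seq = tokenize(train_text, "bpe", bpe)
                test_seq = tokenize(test_text, "bpe", bpe)
            else:
                train_seq = tokenize(train_text, level)
                test_seq = tokenize(test_text, level)
            H = _incremental_bits(train_seq, test_seq, config) / n_v
            if H < 0:
                logger.warning(
                    "dropping negative H_f (lang=%s fold=%d f=%d)", language, test_fold, f
                )
                continue
            rows.append(
                {
                    "language": language,
                    "level": level,
                    "backend": config.backend,
                    "test_fold": test_fold,
                    "f": f,
                    "H": H,
                }
            )
    return pd.DataFrame(rows)


def _series_ppm_incremental(
    fold_verses: dict[int, list[str]],
    language: str,
    schedule: TrainingSchedule,
    config: CompressorConfig,
    level: str,
    n_folds: int,
    n_test_folds: int,
) -> pd.DataFrame:
    """PPM fast path: folds are fed into the model once per rotation and the
    test fold is re-encoded from a state snapshot, so prefixes T_1..T_9
    share all computation.  Bit-identical to the from-scratch evaluation up
    to the language-wide id space (PPM probabilities depend only on
    observed counts, never on the alphabet size)."""
    vocab: dict[str, int] = {}
    fold_ids: dict[int, np.ndarray] = {}
    fold_syms: dict[int, list[str]] = {}
    for fold in range(1, n_folds + 1):
        syms = tokenize(" ".join(fold_verses[fold]), level).symbols
        fold_syms[fold] = syms
        fold_ids[fold] = _coded_ids(syms, vocab)
    V = max(len(vocab), 1)
    rows = []
    for test_fold in range(1, n_test_folds + 1):
        train_order = schedule.order[test_fold]
        n_v = len(fold_verses[test_fold])
        test_ids = fold_ids[test_fold]
        model = PPMModel(
            V,
            order=config.order,
            base_alphabet_size=config.base_alphabet_size or 2**32,
            memory_cap=config.memory_cap,
        )
        first_app: dict[str, int] = {}
        for f, fold in enumerate(train_order, start=1):
            model.feed(fold_ids[fold])
            for s in fold_syms[fold]:
                first_app.setdefault(s, len(first_app))
            bits_test = float(model.peek(test_ids).sum())
            both = dict(first_app)
            for s in fold_syms[test_fold]:
                both.setdefault(s, len(both))
            dH = (
                bits_test
                + SymbolTable(mapping=both).serialized_bits()
                - SymbolTable(mapping=first_app).serialized_bits()
            )
            H = dH / n_v
            if H < 0:
                logger.warning(
                    "dropping negative H_f (lang=%s fold=%d f=%d)", language, test_fold, f
                )
                continue
            rows.append(
                {
                    "language": language,
                    "level": level,
                    "backend": config.backend,
                    "test_fold": test_fold,
                    "f": f,
                    "H": H,
                }
            )
    return pd.DataFrame(rows)


def _incremental_bits(
    train_seq: SymbolSequence, test_seq: SymbolSequence, config: CompressorConfig
) -> float:
    """R(T_f T_test) - R(T_f), both including symbol-table bits."""
    if config.backend == "ppm":
        vocab: dict[str, int] = {}
        train_ids = _coded_ids(train_seq.symbols, vocab)
        test_ids = _coded_ids(test_seq.symbols, vocab)
        V = max(len(vocab), 1)
        model = PPMModel(
            V,
            order=config.order,
            base_alphabet_size=config.base_alphabet_size or 2**32,
            memory_cap=config.memory_cap,
        )
        bits_train = float(model.feed(train_ids).sum())
        bits_test = float(model.peek(test_ids).sum())
        # tables for T_f and T_f+T_test differ by the types first seen in test
        t_train = SymbolTable(mapping=_first_appearance_table(train_seq.symbols))
        t_both = SymbolTable(
            mapping=_first_appearance_table(train_seq.symbols + test_seq.symbols)
        )
        return (bits_train + bits_test + t_both.serialized_bits()) - (
            bits_train + t_train.serialized_bits()
        )
    # external backend: operate on the 4-byte coded byte streams
    train_stream, t_train = encode_symbols(train_seq)
    both = SymbolSequence(level=train_seq.level, symbols=train_seq.symbols + test_seq.symbols)
    both_stream, t_both = encode_symbols(both)
    R_train = backend_codelength(train_stream, config.backend) + t_train.serialized_bits()
    R_both = backend_codelength(both_stream, config.backend) + t_both.serialized_bits()
    return R_both - R_train


def _first_appearance_table(symbols: list[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for s in symbols:
        mapping.setdefault(s, len(mapping))
    return mapping


def corpus_cross_entropies(
    corpus: ParallelCorpus,
    assignment: FoldAssignment,
    schedule: TrainingSchedule,
    config: CompressorConfig | None = None,
    level: str = "word",
    n_test_folds: int | None = None,
) -> pd.DataFrame:
    """Cross-entropy series for every language, concatenated."""
    frames = [
        cross_entropy_series(corpus, lang, assignment, schedule, config, level, n_test_folds)
        for lang in corpus.languages
    ]
    return pd.concat(frames, ignore_index=True)


def fit_slope_model(xent: pd.DataFrame, maxiter: int = 100) -> SlopeModelFit:
    """REML mixed model of log H on log f; per-language slope BLUPs mu.

    Random structure: crossed intercepts for test fold and language plus a
    per-language random slope of log f with unstructured intercept-slope
    covariance.
    """
    df = xent[xent["H"] > 0].copy()
    if df["language"].nunique() < 2 or df["f"].nunique() < 2:
        raise ValueError("need >= 2 languages and >= 2 distinct f values")
    y = np.log(df["H"].to_numpy())
    logf = np.log(df["f"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(df)), logf])
    Z_lang, lang_levels = indicator_matrix(df["language"])
    Z_fold, fold_levels = indicator_matrix(df["test_fold"])
    pair = PairedComponent(
        name="language",
        Z_intercept=Z_lang,
        Z_slope=Z_lang * logf[:, None],
        levels=lang_levels,
    )
    comps = [IIDComponent(name="test_fold", Z=Z_fold, levels=fold_levels)]
    res = fit_mixed_model(y, X, comps, pair, method="reml", maxiter=maxiter)
    if not np.isfinite(res.loglik):
        raise RuntimeError("slope model failed to produce a finite likelihood")
    mu = pd.Series(res.blups["language_slope"], index=lang_levels, name="mu")
    sigma2_mu = float(res.varcomps["language"][1, 1])
    return SlopeModelFit(
        fixed_intercept=float(res.beta[0]),
        fixed_slope=float(res.beta[1]),
        mu=mu,
        sigma2_mu=sigma2_mu,
        varcomps=res.varcomps,
        result=res,
    )
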