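"""Verse-aligned parallel corpora, tokenization, BPE and symbol coding.

The corpus dialect is one UTF-8 TSV per language with columns
``book``, ``chapter``, ``verse``, ``text``; a corpus directory holds
``<language>.tsv`` files.  Corpora are pre-tokenized: the word boundary is a
single space.  Word and sub-word symbol types are mapped to fixed-width
4-byte codes before compression so that code lengths are comparable across
scripts and vocabulary sizes.
"""

from __future__ import annotations

import logging
import lzma
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VerseKey = tuple[str, int, int]

METADATA_COLUMNS = [
    "language",
    "family",
    "subfamily",
    "sub_branch",
    "macro_area",
    "country",
    "script",
    "egids",
    "population",
    "longitude",
    "latitude",
    "n_countries",
    "range_size",
    "altitude",
    "distance_to_water",
    "climate_pc1",
    "climate_pc2",
]


class CorpusError(ValueError):
    """Malformed or empty corpus input."""


@dataclass
class ParallelCorpus:
    """Fully parallel verse-aligned corpus.

    ``verses`` maps each (book, chapter, verse) key to a ``{language: text}``
    dict; after construction every key is present for every language and the
    key order is identical across languages.
    """

    languages: list[str]
    verses: dict[VerseKey, dict[str, str]]

    def __post_init__(self) -> None:
        self.languages = sorted(self.languages)
        self.verses = dict(sorted(self.verses.items()))
        langset = set(self.languages)
        for key, texts in self.verses.items():
            if set(texts) != langset:
                missing = langset - set(texts)
                raise CorpusError(f"verse {key} missing languages {sorted(missing)}")

    @property
    def verse_keys(self) -> list[VerseKey]:
        return list(self.verses)

    @property
    def books(self) -> list[str]:
        return sorted({k[0] for k in self.verses})

    def language_text(self, language: str, keys: Iterable[VerseKey] | None = None) -> list[str]:
        """Verse texts of one language, in verse-key order."""
        keys = self.verse_keys if keys is None else list(keys)
        return [self.verses[k][language] for k in keys]


@dataclass
class SymbolSequence:
    """Tokenized text: ordered symbol-type strings at a given level."""

    level: str  # word | character | bpe
    symbols: list[str]

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def L(self) -> int:
        return len(self.symbols)


_TABLE_FILTERS = [{"id": lzma.FILTER_LZMA2, "dict_size": 1 << 16}]


def _table_compress(payload: bytes) -> bytes:
    return lzma.compress(payload, format=lzma.FORMAT_RAW, filters=_TABLE_FILTERS)


@dataclass
class SymbolTable:
    """Bijection between symbol-type strings and fixed-width 4-byte codes."""

    mapping: dict[str, int]  # symbol -> integer code (encoded as 4 bytes, big endian)

    @property
    def C(self) -> int:
        return len(self.mapping)

    @property
    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.mapping.items()}

    def serialized_bits(self, compress=None) -> int:
        """Compressed size in bits of the serialized mapping.

        The mapping is serialized as a sorted two-column table
        (``symbol\\tcode``) and compressed by ``compress``.  The default is
        a raw lzma stream with a 64 KiB dictionary: symbol tables are tiny
        and a small dictionary avoids paying a large allocation per table
        while compressing such payloads at least as well as the maximum
        preset.  Empty tables still cost > 0 bits.
        """
        payload = "\n".join(
            f"{sym}\t{code}" for sym, code in sorted(self.mapping.items())
        ).encode("utf-8")
        if compress is None:
            compress = _table_compress
        return 8 * len(compress(payload))


@dataclass
class BPEModel:
    """Ordered pair-merge rules learned from training data only."""

    merges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_merges(self) -> int:
        return len(self.merges)


# ---------------------------------------------------------------------------
# corpus reading / writing


def _parse_verse_tsv(path: Path) -> dict[VerseKey, str]:
    records: dict[VerseKey, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusError(
                    f"{path.name}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            book, chapter, verse, text = parts
            try:
                key = (book, int(chapter), int(verse))
            except ValueError as exc:
                raise CorpusError(f"{path.name}:{lineno}: non-integer chapter/verse") from exc
            records[key] = text
    return records


def read_parallel_corpus(path: str | Path, format: str = "verse-tsv") -> ParallelCorpus:
    """Read a directory of per-language verse TSVs into a parallel corpus.

    Verse keys not present in every language are dropped (count logged).
    Raises :class:`CorpusError` on malformed records or if no complete verse
    survives.
    """
    if format != "verse-tsv":
        raise ValueError(f"unknown corpus format: {format!r}")
    path = Path(path)
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise CorpusError(f"no *.tsv corpus files under {path}")
    per_lang = {f.stem: _parse_verse_tsv(f) for f in files}
    languages = sorted(per_lang)
    common = set.intersection(*(set(v) for v in per_lang.values()))
    n_all = len(set.union(*(set(v) for v in per_lang.values())))
    dropped = n_all - len(common)
    if dropped:
        logger.warning("dropped %d incomplete verse keys (of %d)", dropped, n_all)
    if not common:
        raise CorpusError("no verse key is complete across all languages")
    verses = {k: {lang: per_lang[lang][k] for lang in languages} for k in sorted(common)}
    return ParallelCorpus(languages=languages, verses=verses)


def write_parallel_corpus(corpus: ParallelCorpus, path: str | Path) -> None:
    """Write one ``<language>.tsv`` per language under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for lang in corpus.languages:
        with open(path / f"{lang}.tsv", "w", encoding="utf-8") as fh:
            for (book, chap, verse), texts in corpus.verses.items():
                fh.write(f"{book}\t{chap}\t{verse}\t{texts[lang]}\n")


# ---------------------------------------------------------------------------
# tokenization


def tokenize(text: str, level: str, bpe_model: BPEModel | None = None) -> SymbolSequence:
    """Tokenize pre-tokenized text at word, character or BPE level.

    Word level splits on single spaces; character level yields one symbol per
    code point; BPE applies the model's merges greedily in learned order
    within each word.
    """
    if level == "word":
        symbols = [w for w in text.split(" ") if w]
    elif level == "character":
        symbols = list(text)
    elif level == "bpe":
        if bpe_model is None:
            raise ValueError("level='bpe' requires a bpe_model")
        symbols = []
        for word in text.split(" "):
            if word:
                symbols.extend(_apply_bpe(word, bpe_model))
    else:
        raise ValueError(f"unknown tokenization level: {level!r}")
    return SymbolSequence(level=level, symbols=symbols)


def _apply_bpe(word: str, model: BPEModel) -> list[str]:
    units = list(word)
    for left, right in model.merges:
        if len(units) < 2:
            break
        merged: list[str] = []
        i = 0
        while i < len(units):
            if i + 1 < len(units) and units[i] == left and units[i + 1] == right:
                merged.append(left + right)
                i += 2
            else:
                merged.append(units[i])
                i += 1
        units = merged
    return units


def learn_bpe(training_text: Iterable[str]) -> BPEModel:
    """Learn byte-pair merges from training text only.

    The number of merges is ``floor(0.4 * C)`` where ``C`` is the number of
    distinct word types in the training data.  Each merge joins the most
    frequent adjacent unit pair (frequency weighted by word-token counts);
    ties break lexicographically on the pair, for determinism.
    """
    word_counts: Counter[str] = Counter()
    for chunk in training_text:
        word_counts.update(w for w in chunk.split(" ") if w)
    if not word_counts:
        raise ValueError("empty training text")
    n_merges = int(0.4 * len(word_counts))
    vocab: dict[tuple[str, ...], int] = {
        tuple(word): count for word, count in word_counts.items()
    }
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        pair_counts: Counter[tuple[str, str]] = Counter()
        for units, count in vocab.items():
            for a, b in zip(units, units[1:]):
                pair_counts[(a, b)] += count
        if not pair_counts:
            break
        best = min(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        merges.append(best)
        new_vocab: dict[tuple[str, ...], int] = {}
        for units, count in vocab.items():
            merged: list[str] = []
            i = 0
            while i < len(units):
                if i + 1 < len(units) and (units[i], units[i + 1]) == best:
                    merged.append(units[i] + units[i + 1])
                    i += 2
                else:
                    merged.append(units[i])
                    i += 1
            new_vocab[tuple(merged)] = new_vocab.get(tuple(merged), 0) + count
        vocab = new_vocab
    return BPEModel(merges=merges)


# ---------------------------------------------------------------------------
# fixed-width symbol coding


def encode_symbols(seq: SymbolSequence) -> tuple[bytes, SymbolTable]:
    """Map each distinct symbol type to a unique 4-byte code.

    Codes are assigned in first-appearance order; the byte stream is the
    concatenation of big-endian 4-byte codes (length ``4 * L``).
    """
    mapping: dict[str, int] = {}
    out = bytearray()
    for sym in seq.symbols:
        code = mapping.setdefault(sym, len(mapping))
        out += code.to_bytes(4, "big")
    return bytes(out), SymbolTable(mapping=mapping)


def decode_symbols(stream: bytes, table: SymbolTable, level: str = "word") -> SymbolSequence:
    """Invert :func:`encode_symbols` exactly."""
    if len(stream) % 4:
        raise ValueError("stream length not a multiple of 4")
    inv = table.inverse
    symbols = [
        inv[int.from_bytes(stream[i : i + 4], "big")] for i in range(0, len(stream), 4)
    ]
    return SymbolSequence(level=level, symbols=symbols)


def symbol_ids(seq: SymbolSequence) -> tuple[np.ndarray, SymbolTable]:
    """Integer-id view of a symbol sequence (first-appearance coding)."""
    mapping: dict[str, int] = {}
    ids = np.empty(len(seq.symbols), dtype=np.int64)
    for i, sym in enumerate(seq.symbols):
        ids[i] = mapping.setdefault(sym, len(mapping))
    return ids, SymbolTable(mapping=mapping)


# ---------------------------------------------------------------------------
# comparative-analysis inputs


def read_distance_matrix(path: str | Path, tol: float = 1e-8) -> pd.DataFrame:
    """Read a square labeled TSV distance matrix; validate symmetry/diagonal."""
    d = pd.read_csv(path, sep="\t", index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    if list(d.index) != list(d.columns):
        raise ValueError("distance matrix row/column labels differ")
    arr = d.to_numpy(dtype=float)
    if np.max(np.abs(arr - arr.T)) > tol:
        raise ValueError("distance matrix asymmetric beyond tolerance")
    if np.max(np.abs(np.diag(arr))) > tol:
        raise ValueError("distance matrix diagonal not zero")
    if (arr < -tol).any():
        raise ValueError("negative distances")
    return d


def write_distance_matrix(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-language metadata table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(path, sep=sep)
    if "language" not in meta.columns:
        raise ValueError("metadata requires a 'language' column")
    if (meta.get("population", pd.Series(dtype=float)) <= 0).any():
        raise ValueError("population must be positive")
    return meta.set_index("language", drop=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def load_comparative_inputs(
    metadata_path: str | Path,
    tree_path: str | Path,
    matrix_paths: Sequence[str | Path] = (),
) -> tuple[pd.DataFrame, dendropy.Tree, list[pd.DataFrame], list[str]]:
    """Load and align metadata, tree and distance matrices by language id.

    Returns objects restricted to the common language set plus the sorted
    list of dropped languages.  Raises if no language is common to all
    inputs.
    """
    meta = read_metadata(metadata_path)
    tree = read_tree(tree_path)
    matrices = [read_distance_matrix(p) for p in matrix_paths]
    sets = [set(meta.index), {t.label for t in tree.taxon_namespace}]
    sets += [set(m.index) for m in matrices]
    common = sorted(set.intersection(*sets))
    if not common:
        raise ValueError("no language common to all comparative inputs")
    dropped = sorted(set.union(*sets) - set(common))
    if dropped:
        logger.warning("dropped %d languages absent from some input", len(dropped))
    meta = meta.loc[common]
    keep = {t for t in tree.taxon_namespace if t.label in set(common)}
    if len(keep) < len(tree.taxon_namespace):
        tree = tree.extract_tree_with_taxa(taxa=keep)
    matrices = [m.loc[common, common] for m in matrices]
    return meta, tree, matrices, dropped
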