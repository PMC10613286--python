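import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glottolearn.corpus_io import (
    BPEModel,
    CorpusError,
    ParallelCorpus,
    SymbolSequence,
    decode_symbols,
    encode_symbols,
    learn_bpe,
    load_comparative_inputs,
    read_distance_matrix,
    read_parallel_corpus,
    tokenize,
    write_parallel_corpus,
)


def _mini_corpus():
    verses = {
        ("b01", 1, 1): {"aaa": "x y", "bbb": "u v"},
        ("b01", 1, 2): {"aaa": "y y", "bbb": "v u"},
        ("b02", 1, 1): {"aaa": "x", "bbb": "w"},
    }
    return ParallelCorpus(["aaa", "bbb"], verses)


class TestParallelCorpus:
    def test_roundtrip_preserves_structure(self, tmp_path):
        corpus = _mini_corpus()
        write_parallel_corpus(corpus, tmp_path)
        back = read_parallel_corpus(tmp_path)
        assert back.languages == corpus.languages
        assert back.verses == corpus.verses

    def test_incomplete_verses_dropped(self, tmp_path):
        corpus = _mini_corpus()
        write_parallel_corpus(corpus, tmp_path)
        # remove one verse from one language only
        lines = (tmp_path / "bbb.tsv").read_text().splitlines()
        (tmp_path / "bbb.tsv").write_text("\n".join(lines[:-1]) + "\n")
        back = read_parallel_corpus(tmp_path)
        assert len(back.verses) == 2
        assert ("b02", 1, 1) not in back.verses

    def test_malformed_record_reports_line(self, tmp_path):
        (tmp_path / "xxx.tsv").write_text("b01\t1\t1\thello\nbad line\n")
        with pytest.raises(CorpusError, match="xxx.tsv:2"):
            read_parallel_corpus(tmp_path)

    def test_no_complete_verse_is_an_error(self, tmp_path):
        (tmp_path / "aaa.tsv").write_text("b01\t1\t1\thello\n")
        (tmp_path / "bbb.tsv").write_text("b01\t1\t2\tworld\n")
        with pytest.raises(CorpusError):
            read_parallel_corpus(tmp_path)

    def test_missing_language_in_constructor(self):
        with pytest.raises(CorpusError):
            ParallelCorpus(["a", "b"], {("b01", 1, 1): {"a": "x"}})


class TestTokenize:
    def test_word_level(self):
        assert tokenize("a b a", "word").symbols == ["a", "b", "a"]
        assert tokenize("a b a", "word").L == 3

    def test_character_level(self):
        assert tokenize("ab", "character").symbols == ["a", "b"]

    def test_bpe_applies_merges_in_order(self):
        model = BPEModel(merges=[("l", "o"), ("lo", "w")])
        assert tokenize("low lower", "bpe", model).symbols == ["low", "low", "e", "r"]

    def test_bpe_without_model_is_usage_error(self):
        with pytest.raises(ValueError):
            tokenize("a", "bpe")


class TestLearnBPE:
    def test_merge_count_is_04C(self):
        # 10 distinct word types -> floor(0.4 * 10) = 4 merges
        words = [f"w{i}x" for i in range(10)]
        model = learn_bpe([" ".join(words)])
        assert model.n_merges == 4

    def test_single_type_yields_zero_merges(self):
        assert learn_bpe(["aa aa aa"]).n_merges == 0

    def test_first_merge_matches_hand_count(self):
        # 4 word types -> 1 merge; pair counts by hand: l-o and o-w tie at 4,
        # lexicographic tie-break picks ("l", "o")
        model = learn_bpe(["low low lower lowest wide"])
        assert model.n_merges == 1
        assert model.merges[0] == ("l", "o")

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            learn_bpe([""])

    def test_deterministic(self):
        text = ["the cat sat on the mat", "the bat"]
        assert learn_bpe(text).merges == learn_bpe(text).merges


class TestSymbolCoding:
    def test_stream_length_and_type_count(self):
        stream, table = encode_symbols(SymbolSequence("word", ["a", "b", "a"]))
        assert len(stream) == 12
        assert table.C == 2

    def test_empty_sequence(self):
        stream, table = encode_symbols(SymbolSequence("word", []))
        assert stream == b"" and table.C == 0
        assert table.serialized_bits() > 0

    def test_roundtrip_random_sequence(self):
        rng = np.random.default_rng(0)
        symbols = [f"s{int(i)}" for i in rng.integers(0, 50, size=500)]
        stream, table = encode_symbols(SymbolSequence("word", symbols))
        assert decode_symbols(stream, table).symbols == symbols

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.text(alphabet=st.characters(min_codepoint=33, max_codepoint=1000), min_size=1),
            max_size=60,
        )
    )
    def test_encode_decode_is_lossless_for_any_symbols(self, symbols):
        stream, table = encode_symbols(SymbolSequence("word", symbols))
        assert len(stream) == 4 * len(symbols)
        assert table.C == len(set(symbols))
        assert decode_symbols(stream, table).symbols == symbols

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="abcdef", min_size=1, max_size=8), min_size=1, max_size=30))
    def test_word_tokenization_inverts_space_join(self, words):
        text = " ".join(words)
        assert tokenize(text, "word").symbols == words


class TestComparativeInputs:
    def test_alignment_drops_unshared_languages(self, tmp_path):
        import pandas as pd

        meta = pd.DataFrame(
            {
                "language": list("ABCDE"),
                "population": [10, 20, 30, 40, 50],
                "latitude": [0.0] * 5,
                "longitude": [0.0] * 5,
            }
        )
        meta.to_csv(tmp_path / "meta.csv", index=False)
        (tmp_path / "tree.nwk").write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        meta2, tree, mats, dropped = load_comparative_inputs(
            tmp_path / "meta.csv", tmp_path / "tree.nwk"
        )
        assert sorted(meta2.index) == list("ABCD")
        assert dropped == ["E"]

    def test_asymmetric_matrix_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("\tA\tB\nA\t0\t1.0\nB\t2.0\t0\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_distance_matrix(tmp_path / "d.tsv")

    def test_newick_patristic_distance(self, tmp_path):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,(B:1,C:1):1);", schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert len(tree.leaf_nodes()) == 3
        assert pdm.patristic_distance(taxa["B"], taxa["C"]) == pytest.approx(2.0)
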