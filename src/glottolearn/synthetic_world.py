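"""A fully synthetic world of languages with known ground truth.

The generator produces everything the downstream pipeline consumes — a Yule
phylogeny, per-language Markov text sources with closed-form entropy rates,
speaker populations with a programmable effect on learning difficulty,
coordinates, nested metadata and distance matrices — so that parameter
recovery can be checked end to end.

Text sources are order-``k`` Markov chains whose transition rows are cyclic
shifts of one fixed base distribution.  This makes the chain doubly
stochastic (uniform stationary distribution) and its entropy rate exactly
the entropy of the base distribution, known in closed form.  Learning
difficulty is realized through vocabulary size: a larger alphabet means
more transition parameters to estimate from the same amount of text, so
empirical compression rates converge more slowly while the entropy rate is
held fixed across languages.

Trait orientation: the latent trait stored as ``learnability`` points the
same way as the fitted difficulty measures ``b`` and ``mu`` (higher =
easier / faster learning), so the population effect ``beta_true`` injected
here is recovered with the same sign by the downstream regressions.
``d_true`` (higher = slower convergence) is its rank-based inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from glottolearn.corpus_io import ParallelCorpus


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    Defaults are the conditions used throughout the package's own
    validation: 60 languages, 10 books of 50 verses (500 parallel verses),
    a mean of 12 word symbols per verse, a population effect of -0.3 on the
    learnability trait, and moderate phylogenetic signal and noise.
    """

    n_languages: int = 60
    n_verses: int = 500
    n_books: int = 10
    verse_length: float = 12.0
    beta_true: float = -0.3
    sigma_phylo: float = 0.5
    sigma_noise: float = 0.5
    vocab_range: tuple[int, int] = (6, 30)
    order_range: tuple[int, int] = (1, 1)
    entropy_rate: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_languages < 2 or self.n_verses < 1 or self.n_books < 1:
            raise ValueError("counts must be positive (and >= 2 languages)")
        if self.sigma_phylo < 0 or self.sigma_noise < 0:
            raise ValueError("sigma values must be >= 0")


@dataclass
class LanguageSource:
    """Markov text source with closed-form entropy rate.

    Transition rule: ``x_t = (x_{t-1} + ... + x_{t-order} + j_t) mod V``
    with ``j_t`` drawn iid from ``base``; entropy rate = H(base) bits.
    """

    vocab: int
    order: int
    base: np.ndarray

    @property
    def h_true(self) -> float:
        p = self.base[self.base > 0]
        return float(-(p * np.log2(p)).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        jumps = rng.choice(self.vocab, size=n, p=self.base)
        if self.order == 0:
            return jumps.astype(np.int64)
        state = rng.integers(0, self.vocab, size=self.order)
        if self.order == 1:
            x0 = int(state[0])
            return ((x0 + np.cumsum(jumps)) % self.vocab).astype(np.int64)
        out = np.empty(n, dtype=np.int64)
        buf = list(state)
        for t in range(n):
            out[t] = (sum(buf) + jumps[t]) % self.vocab
            buf.pop(0)
            buf.append(out[t])
        return out


def base_distribution(vocab: int, entropy_bits: float) -> np.ndarray:
    """Geometric-family distribution over ``vocab`` symbols with the given
    entropy (bisection on the ratio; capped at uniform = log2(vocab))."""
    if entropy_bits >= np.log2(vocab) - 1e-12:
        return np.full(vocab, 1.0 / vocab)
    if entropy_bits <= 0:
        raise ValueError("entropy_bits must be positive")

    def entropy_of(q: float) -> float:
        w = q ** np.arange(vocab)
        p = w / w.sum()
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    lo, hi = 1e-9, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if entropy_of(mid) < entropy_bits:
            lo = mid
        else:
            hi = mid
    w = (0.5 * (lo + hi)) ** np.arange(vocab)
    return w / w.sum()


def make_source(vocab: int, order: int, entropy_bits: float) -> LanguageSource:
    return LanguageSource(vocab=vocab, order=order, base=base_distribution(vocab, entropy_bits))


# ---------------------------------------------------------------------------
# phylogeny


def simulate_phylogeny(n_languages: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree scaled to unit height.

    Tips are labeled ``L001..``; deterministic given the seed.
    """
    if n_languages < 2:
        raise ValueError("need at least 2 languages")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.split_time = 0.0
    tips = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        tips.append(child)
    t = 0.0
    while len(tips) < n_languages:
        k = len(tips)
        t += rng.exponential(1.0 / k)
        node = tips.pop(int(rng.integers(k)))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            tips.append(child)
    t_end = t + rng.exponential(1.0 / n_languages)
    for tip in tips:
        tip.split_time = t_end
    # labels in left-to-right leaf order; heights normalized to 1
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"L{i + 1:03d}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.split_time - node.parent_node.split_time) / t_end
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def brownian_covariance(tree: dendropy.Tree, labels: list[str] | None = None) -> pd.DataFrame:
    """Shared root-to-MRCA path lengths: the Brownian trait covariance."""
    labels = labels or tip_labels(tree)
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else depth[node.parent_node]
        depth[node] = parent_depth + (node.edge.length or 0.0)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._below = [idx[node.taxon.label]]
            C[node._below[0], node._below[0]] = depth[node]
        else:
            kids = [c._below for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = depth[node]
            node._below = [i for grp in kids for i in grp]
    return pd.DataFrame(C, index=labels, columns=labels)


def sample_brownian(C: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.zeros(C.shape[0])
    jitter = 1e-10 * np.eye(C.shape[0])
    L = np.linalg.cholesky(sigma**2 * C + jitter)
    return L @ rng.standard_normal(C.shape[0])


# ---------------------------------------------------------------------------
# traits and metadata


def _clade_labels(tree: dendropy.Tree, depth_cut: float, prefix: str) -> dict[str, str]:
    """Group tips by the lineage crossing ``depth_cut`` (tree height 1)."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else depth[node.parent_node]
        depth[node] = parent_depth + (node.edge.length or 0.0)
    groups: dict[str, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else depth[node.parent_node]
        if parent_depth < depth_cut <= depth[node] or (
            node.is_leaf() and depth[node] < depth_cut
        ):
            counter += 1
            label = f"{prefix}{counter:02d}"
            if node.is_leaf():
                groups[node.taxon.label] = label
            else:
                for leaf in node.leaf_iter():
                    groups[leaf.taxon.label] = label
    return groups


def simulate_language_traits(
    tree: dendropy.Tree, config: WorldConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sociodemographic metadata plus a truth table of all latent values.

    Populations follow Brownian motion on the tree (log scale, mapped into
    [1e2, 1e9]); the learnability trait is
    ``beta_true * log(population) + phylogenetic component + noise``;
    families/subfamilies/sub-branches come from clade cuts at depths
    0.25/0.5/0.75; macro areas and countries from spatial clustering of
    coordinates sampled with phylogenetic signal (countries nested within
    macro areas by construction).
    """
    labels = tip_labels(tree)
    n = len(labels)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    C = brownian_covariance(tree, labels).to_numpy()

    raw = sample_brownian(C, 1.0, rng) + 0.3 * rng.standard_normal(n)
    span = raw.max() - raw.min()
    lo, hi = np.log(1e2), np.log(1e9)
    log_pop = lo + (raw - raw.min()) / (span if span > 0 else 1.0) * (hi - lo)
    population = np.exp(log_pop)

    learnability = (
        config.beta_true * log_pop
        + sample_brownian(C, config.sigma_phylo, rng)
        + config.sigma_noise * rng.standard_normal(n)
    )

    # harder (lower learnability) -> larger vocabulary -> slower convergence
    ranks = np.argsort(np.argsort(-learnability))  # 0 = easiest
    vmin, vmax = config.vocab_range
    vocab = np.round(vmin + ranks / max(n - 1, 1) * (vmax - vmin)).astype(int)
    omin, omax = config.order_range
    order = np.where(ranks < n // 2, omin, omax) if omax > omin else np.full(n, omin)
    d_true = (order + 1) * np.log2(vocab)

    fam = _clade_labels(tree, 0.25, "F")
    sub = _clade_labels(tree, 0.50, "S")
    br = _clade_labels(tree, 0.75, "B")
    family = [fam[l] for l in labels]
    subfamily = [f"{fam[l]}.{sub[l]}" for l in labels]  # explicit nesting
    sub_branch = [f"{fam[l]}.{sub[l]}.{br[l]}" for l in labels]

    lat_raw = sample_brownian(C, 1.0, rng)
    lon_raw = sample_brownian(C, 1.0, rng)

    def rescale(x, a, b):
        s = x.max() - x.min()
        return a + (x - x.min()) / (s if s > 0 else 1.0) * (b - a)

    latitude = rescale(lat_raw, -55.0, 65.0)
    longitude = rescale(lon_raw, -175.0, 175.0)

    coords = np.column_stack([latitude, longitude])
    k_area = min(4, n)
    km = KMeans(n_clusters=k_area, n_init=10, random_state=int(rng.integers(2**31)))
    area_idx = km.fit_predict(coords)
    macro_area = np.array([f"MA{i + 1}" for i in area_idx])
    country = np.empty(n, dtype=object)
    for a in np.unique(area_idx):
        mask = area_idx == a
        k_c = min(3, int(mask.sum()))
        km_c = KMeans(n_clusters=k_c, n_init=10, random_state=int(rng.integers(2**31)))
        sub_idx = km_c.fit_predict(coords[mask])
        country[mask] = [f"MA{a + 1}_C{j + 1}" for j in sub_idx]

    fam_levels = sorted(set(family))
    script = [f"SC{fam_levels.index(f) % 5 + 1}" for f in family]
    egids = np.clip(
        np.round(10 - (log_pop - lo) / (hi - lo) * 9 + rng.normal(0, 0.7, n)), 0, 10
    ).astype(int)
    n_countries = 1 + rng.poisson(np.clip((log_pop - lo) / 5.0, 0, None))
    range_size = np.exp(rng.normal(6, 1, n) + 0.3 * (log_pop - log_pop.mean()))
    altitude = np.exp(rng.normal(5.5, 1, n))
    distance_to_water = np.exp(rng.normal(3, 1, n))
    climate_pc1 = -np.abs(latitude) / 30.0 + rng.normal(0, 0.5, n)
    climate_pc2 = longitude / 100.0 + rng.normal(0, 0.5, n)

    meta = pd.DataFrame(
        {
            "language": labels,
            "family": family,
            "subfamily": subfamily,
            "sub_branch": sub_branch,
            "macro_area": macro_area,
            "country": country,
            "script": script,
            "egids": egids,
            "population": population,
            "longitude": longitude,
            "latitude": latitude,
            "n_countries": n_countries,
            "range_size": range_size,
            "altitude": altitude,
            "distance_to_water": distance_to_water,
            "climate_pc1": climate_pc1,
            "climate_pc2": climate_pc2,
        }
    ).set_index("language", drop=False)
    truth = pd.DataFrame(
        {
            "language": labels,
            "log_population": log_pop,
            "learnability": learnability,
            "d_true": d_true,
            "vocab": vocab,
            "order": order,
        }
    ).set_index("language", drop=False)
    return meta, truth


# ---------------------------------------------------------------------------
# parallel corpus


def synthesize_parallel_corpus(
    truth: pd.DataFrame, config: WorldConfig, seed: int | None = None
) -> tuple[ParallelCorpus, dict[str, LanguageSource]]:
    """Sample each language's verses from its Markov source.

    Verse keys (book/chapter/verse) are identical across languages, keeping
    the corpus fully parallel; texts and verse lengths differ per language
    (as translations of the same content do).  Symbols render as word
    tokens ``w000..``, space separated.
    """
    master = np.random.default_rng(config.seed if seed is None else seed)
    per_book = int(np.ceil(config.n_verses / config.n_books))
    keys = []
    for v in range(config.n_verses):
        book = f"b{v // per_book + 1:02d}"
        keys.append((book, 1, v % per_book + 1))
    sources: dict[str, LanguageSource] = {}
    verses: dict = {k: {} for k in keys}
    lang_seeds = master.integers(0, 2**31, size=len(truth))
    for (lang, row), lseed in zip(truth.iterrows(), lang_seeds):
        src = make_source(int(row["vocab"]), int(row["order"]), config.entropy_rate)
        sources[lang] = src
        rng = np.random.default_rng(int(lseed))
        lengths = np.maximum(1, rng.poisson(config.verse_length, size=config.n_verses))
        stream = src.sample(int(lengths.sum()), rng)
        pos = 0
        for key, ln in zip(keys, lengths):
            chunk = stream[pos : pos + ln]
            pos += ln
            verses[key][lang] = " ".join(f"w{c:03d}" for c in chunk)
    corpus = ParallelCorpus(languages=list(truth.index), verses=verses)
    return corpus, sources


# ---------------------------------------------------------------------------
# whole-world bundle


@dataclass
class World:
    config: WorldConfig
    tree: dendropy.Tree
    metadata: pd.DataFrame
    truth: pd.DataFrame
    corpus: ParallelCorpus
    sources: dict[str, LanguageSource] = field(default_factory=dict)
    geo_distance: pd.DataFrame | None = None
    lexical_distance: pd.DataFrame | None = None


def generate_world(config: WorldConfig) -> World:
    """Tree, traits, corpus and both distance matrices from one config/seed."""
    from glottolearn.comparative_stats import haversine_matrix

    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_corpus, s_lex = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4))
    tree = simulate_phylogeny(config.n_languages, s_tree)
    meta, truth = simulate_language_traits(tree, config, seed=s_traits)
    corpus, sources = synthesize_parallel_corpus(truth, config, seed=s_corpus)
    geo = haversine_matrix(meta["latitude"].to_numpy(), meta["longitude"].to_numpy(), labels=list(meta.index))
    pat = brownian_covariance(tree)  # reuse depths for patristic below
    labels = list(meta.index)
    depths = np.diag(pat.loc[labels, labels].to_numpy())
    mrca = pat.loc[labels, labels].to_numpy()
    patristic = depths[:, None] + depths[None, :] - 2 * mrca
    rng = np.random.default_rng(s_lex)
    noise = np.abs(rng.normal(0, 0.05, size=patristic.shape))
    noise = 0.5 * (noise + noise.T)
    lex = patristic + noise
    np.fill_diagonal(lex, 0.0)
    lexical = pd.DataFrame(lex, index=labels, columns=labels)
    return World(
        config=config,
        tree=tree,
        metadata=meta,
        truth=truth,
        corpus=corpus,
        sources=sources,
        geo_distance=geo,
        lexical_distance=lexical,
    )


def write_world(world: World, path) -> None:
    """Emit the world in the on-disk formats corpus_io reads."""
    from pathlib import Path

    from glottolearn.corpus_io import write_distance_matrix, write_parallel_corpus

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_parallel_corpus(world.corpus, path / "corpus")
    world.metadata.to_csv(path / "metadata.csv", index=False)
    world.truth.to_csv(path / "truth.csv", index=False)
    world.tree.write(path=str(path / "tree.nwk"), schema="newick")
    if world.geo_distance is not None:
        write_distance_matrix(world.geo_distance, path / "geo_distance.tsv")
    if world.lexical_distance is not None:
        write_distance_matrix(world.lexical_distance, path / "lexical_distance.tsv")
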