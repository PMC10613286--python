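"""End-to-end orchestration: simulate, Study 1, Study 2, recovery benchmark.

Every run is a deterministic function of one master seed; all stage seeds
are spawned from it.  Outputs are plain CSV/JSON files under a run
directory, each run carrying a manifest with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glottolearn import comparative_stats as cs
from glottolearn.compression_lm import CompressorConfig, compression_curve
from glottolearn.corpus_io import symbol_ids, tokenize
from glottolearn.learning_curves import fit_curve
from glottolearn.rotation_xent import (
    assign_folds,
    corpus_cross_entropies,
    fit_slope_model,
    make_training_schedule,
)
from glottolearn.synthetic_world import World, WorldConfig, generate_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    backend: str = "ppm"
    order: int = 2
    level: str = "word"
    n_folds: int = 10
    n_test_folds: int = 5
    n_perm: int = 500
    candidate_tier: str = "small"
    full_enumeration: bool = False
    seed: int = 0
    outdir: str | None = None

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def stage_seeds(self, n: int) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _spec_subset(study: int) -> list[tuple[cs.ModelSpec, cs.ModelSpec]]:
    """A small deterministic slice of the model space for fast FMA runs.

    Single-factor intercept specs for every grouping factor, plus
    intercept+slope variants for the first two factors, plus the
    intercept-only/no-group baseline where the grammar allows it.
    """
    groups = cs.STUDY1_GROUPS if study == 1 else cs.STUDY2_GROUPS
    specs = []
    if study == 1:
        specs.append(cs.ModelSpec(1, ("h", "L"), True, (), ()))
    for g in groups:
        specs.append(cs.ModelSpec(study, ("h", "L") if study == 1 else (), True, (g,), ()))
    for g in groups[:2]:
        specs.append(cs.ModelSpec(study, ("h", "L") if study == 1 else (), True, (g,), (g,)))
    return [(s, s.reduced()) for s in specs]


def _fma_over_specs(
    data: pd.DataFrame,
    outcome: str,
    study: int,
    full_enumeration: bool,
) -> tuple[cs.FMAResult, pd.DataFrame]:
    pairs = (
        cs.enumerate_model_subsets(study) if full_enumeration else _spec_subset(study)
    )
    rows = []
    full_fits = []
    for full_spec, red_spec in pairs:
        full = cs.fit_association_lmer(data, full_spec, outcome)
        red = cs.fit_association_lmer(data, red_spec, outcome)
        cmp = cs.delta_aic_compare(full, red)
        full_fits.append(full)
        rows.append(
            {
                "intercepts": "+".join(full_spec.intercepts),
                "slopes": "+".join(full_spec.slopes),
                "fixed": "+".join(full_spec.fixed),
                "beta": full.beta,
                "se": full.se,
                "aic_full": full.aic,
                "aic_reduced": red.aic,
                "delta_aic": cmp.delta,
                "full_apt": cmp.full_apt,
                "converged": full.converged,
            }
        )
    fma = cs.fma_estimate(full_fits)
    table = pd.DataFrame(rows)
    table["fma_weight"] = fma.weights
    return fma, table


def _write_bundle(outdir: str | None, tables: dict[str, pd.DataFrame], manifest: dict):
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def study1_difficulties(world: World, config: RunConfig) -> pd.DataFrame:
    """Per-language learning-curve fits (h, A, b) on the concatenated text."""
    comp = CompressorConfig(backend=config.backend, order=config.order)
    rows = []
    for lang in world.corpus.languages:
        text = " ".join(world.corpus.language_text(lang))
        seq = tokenize(text, config.level)
        ids, _ = symbol_ids(seq)
        curve = compression_curve(ids, comp, n_checkpoints=20, document=lang, level=config.level)
        fit = fit_curve(curve)
        row = {"language": lang, "level": config.level, "L": len(seq)}
        if fit is None:
            row.update({"h": np.nan, "A": np.nan, "b": np.nan, "rmse": np.nan, "converged": False})
        else:
            row.update({"h": fit.h, "A": fit.A, "b": fit.b, "rmse": fit.rmse, "converged": fit.converged})
        rows.append(row)
    return pd.DataFrame(rows).set_index("language", drop=False)


def run_study1(config: RunConfig) -> dict:
    """Learning curves -> ansatz b -> LMER/FMA -> double selection + test."""
    s_world, s_ds, s_fl = config.stage_seeds(3)
    world = generate_world(dataclasses.replace(config.world, seed=s_world))
    diff = study1_difficulties(world, config)
    data = diff.join(world.metadata.drop(columns=["language"]))
    data = data[data["converged"] & (data["b"] > 0)].copy()
    data["log_population"] = np.log(data["population"])
    data["corpus"] = "synthetic"
    data = cs.standardize_per_corpus(data, ["b", "h", "L"])
    fma, lmer_table = _fma_over_specs(data, "b", 1, config.full_enumeration)

    meta_ds = data.copy()
    # candidates take logs themselves, so give them h and L on the raw scale
    meta_ds["h"] = diff.loc[data.index, "h"]
    meta_ds["L"] = diff.loc[data.index, "L"]
    candidates = cs.build_candidate_set(meta_ds, config.candidate_tier)
    log_b = np.log(diff.loc[data.index, "b"].to_numpy())
    ds = cs.double_selection(
        log_b,
        data["log_population"].to_numpy(),
        candidates,
        cluster_ids=data.index.to_numpy(),
        tier=config.candidate_tier,
        seed=s_ds,
    )
    fl = cs.freedman_lane_test(
        log_b,
        data["log_population"].to_numpy(),
        candidates[ds.selected] if ds.selected else None,
        n_perm=config.n_perm,
        seed=s_fl,
    )
    tables = {
        "difficulty_study1": diff.reset_index(drop=True),
        "lmer_models": lmer_table,
    }
    manifest = {"config_hash": config.hash(), "config": dataclasses.asdict(config)}
    _write_bundle(config.outdir, tables, manifest)
    return {
        "world": world,
        "difficulty": diff,
        "fma": fma,
        "lmer_table": lmer_table,
        "ds": ds,
        "freedman_lane": fl,
        "manifest": manifest,
    }


def study2_difficulties(world: World, config: RunConfig):
    """Rotation cross entropies -> REML slope model.

    Returns (mu, xent table, SlopeModelFit).
    """
    s_folds, s_sched = config.stage_seeds(5)[3:]
    assignment = assign_folds(world.corpus, config.n_folds, seed=s_folds)
    schedule = make_training_schedule(assignment, seed=s_sched)
    comp = CompressorConfig(backend=config.backend, order=config.order)
    xent = corpus_cross_entropies(
        world.corpus, assignment, schedule, comp, config.level, config.n_test_folds
    )
    slope = fit_slope_model(xent)
    return slope.mu, xent, slope


def run_study2(config: RunConfig) -> dict:
    """Folds -> schedules -> cross entropies -> mu -> four inference families."""
    seeds = config.stage_seeds(9)
    s_world, s_ds, s_fl = seeds[0], seeds[5], seeds[6]
    s_sar = seeds[7]
    world = generate_world(dataclasses.replace(config.world, seed=s_world))
    mu, xent, slope = study2_difficulties(world, config)
    meta = world.metadata.loc[mu.index]
    data = meta.copy()
    data["mu"] = mu
    data["log_population"] = np.log(data["population"])
    fma, lmer_table = _fma_over_specs(data, "mu", 2, config.full_enumeration)

    candidates = cs.build_candidate_set(meta, config.candidate_tier)
    ds = cs.double_selection(
        mu.to_numpy(),
        data["log_population"].to_numpy(),
        candidates,
        cluster_ids=meta.index.to_numpy(),
        tier=config.candidate_tier,
        seed=s_ds,
    )
    fl = None
    if config.n_perm > 0:
        fl = cs.freedman_lane_test(
            mu.to_numpy(),
            data["log_population"].to_numpy(),
            candidates[ds.selected] if ds.selected else None,
            n_perm=config.n_perm,
            seed=s_fl,
        )
    pgls = cs.fit_pgls(mu, data["log_population"], world.tree)
    W_geo = cs.inverse_distance_weights(world.geo_distance.loc[mu.index, mu.index])
    W_lex = cs.inverse_distance_weights(world.lexical_distance.loc[mu.index, mu.index])
    sar = cs.fit_sar(mu.to_numpy(), data["log_population"].to_numpy(), W_geo, W_lex)
    sar_perm = None
    if config.n_perm > 0:
        sar_perm = cs.sar_permutation_test(
            mu.to_numpy(),
            data["log_population"].to_numpy(),
            W_geo,
            W_lex,
            n_perm=config.n_perm,
            seed=s_sar,
        )
    mu_table = pd.DataFrame(
        {
            "language": mu.index,
            "level": config.level,
            "backend": config.backend,
            "mu": mu.to_numpy(),
            "n_folds": config.n_folds,
            "n_test_folds": config.n_test_folds,
        }
    )
    tables = {"difficulty_study2": mu_table, "xent": xent, "lmer_models": lmer_table}
    manifest = {"config_hash": config.hash(), "config": dataclasses.asdict(config)}
    _write_bundle(config.outdir, tables, manifest)
    return {
        "world": world,
        "mu": mu,
        "xent": xent,
        "slope": slope,
        "fma": fma,
        "lmer_table": lmer_table,
        "ds": ds,
        "freedman_lane": fl,
        "pgls": pgls,
        "sar": sar,
        "sar_perm": sar_perm,
        "manifest": manifest,
    }


def run_recovery_benchmark(config: RunConfig, n_worlds: int = 20) -> dict:
    """Sign-recovery rates of beta_FMA / beta_DS / beta_PGLS / beta_SAR
    across replicate synthetic worlds, as a machine-readable report."""
    sign = np.sign(config.world.beta_true) or 1.0
    records = []
    base_ss = np.random.SeedSequence(config.seed)
    for w, child in enumerate(base_ss.spawn(n_worlds)):
        sub = dataclasses.replace(
            config, seed=int(child.generate_state(1)[0] % 2**31), outdir=None
        )
        res = run_study2(sub)
        records.append(
            {
                "world": w,
                "beta_fma": res["fma"].beta_fma,
                "beta_ds": res["ds"].beta_ds,
                "beta_pgls": res["pgls"].beta_pgls,
                "beta_sar": res["sar"].beta_sar,
            }
        )
    table = pd.DataFrame(records)
    rates = {
        key: float(np.mean(np.sign(table[key]) == sign))
        for key in ("beta_fma", "beta_ds", "beta_pgls", "beta_sar")
    }
    report = {
        "config_hash": config.hash(),
        "n_worlds": n_worlds,
        "beta_true": config.world.beta_true,
        "sign_recovery": rates,
        "betas": table.to_dict(orient="list"),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "benchmark.json").write_text(json.dumps(report, indent=2))
        table.to_csv(out / "benchmark_betas.csv", index=False)
    return report
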