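"""Synthetic embedding tables with planted, controllable bias.

Each word group may be assigned one latent direction (an orthonormal basis
vector).  In ``random`` mode a word's vector is ``normalize(g + beta * u)``
with ``g`` iid standard normal and ``u`` its group's direction (words with
no direction are pure noise); ``beta = 0`` gives an isotropic null table.
In ``exact-geometry`` mode a word's vector *is* its direction, which
reproduces the analytic extremes of the statistics (associations of +/-1,
effect size +/-2) exactly.

Everything is bit-reproducible from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .benchmarks import AttributeGroup, BenchmarkDataset, TargetSet, term_tokens
from .embeddings import BenchmarkPolicy, EmbeddingTable
from .sdweat import SdweatConfig, run_sdweat
from .weat import WeatConfig, run_weat

__all__ = [
    "SynthGroup",
    "SynthConfig",
    "SynthTable",
    "generate_table",
    "table_for_benchmark",
    "make_synthetic_benchmark",
    "calibration_experiment",
]


@dataclass(frozen=True)
class SynthGroup:
    """A labeled word group, optionally tied to one latent direction index."""

    label: str
    words: tuple[str, ...]
    direction: int | None = None

    def __init__(self, label: str, words: Sequence[str], direction: int | None = None):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "words", tuple(words))
        object.__setattr__(self, "direction", direction)


@dataclass(frozen=True)
class SynthConfig:
    groups: tuple[SynthGroup, ...]
    dim: int = 50
    beta: float = 0.0
    seed: int = 0
    mode: Literal["random", "exact-geometry"] = "random"

    def __init__(self, groups, dim=50, beta=0.0, seed=0, mode="random"):
        object.__setattr__(self, "groups", tuple(groups))
        object.__setattr__(self, "dim", int(dim))
        object.__setattr__(self, "beta", float(beta))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "mode", mode)
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.mode not in ("random", "exact-geometry"):
            raise ValueError(f"unknown mode {self.mode!r}")
        seen: dict[str, int | None] = {}
        for g in self.groups:
            for w in g.words:
                if w in seen and seen[w] != g.direction:
                    raise ValueError(f"word {w!r} assigned to conflicting directions")
                seen[w] = g.direction
        dirs = [g.direction for g in self.groups if g.direction is not None]
        if dirs and max(dirs) >= self.dim:
            raise ValueError("more latent directions than dimensions")


@dataclass
class SynthTable(EmbeddingTable):
    """An embedding table that remembers how it was generated."""

    config: SynthConfig | None = None


def generate_table(config: SynthConfig) -> SynthTable:
    """Deterministically generate a unit-norm table per the config."""
    rng = np.random.default_rng(config.seed)
    entries: dict[str, np.ndarray] = {}
    basis = np.eye(config.dim)
    for g in config.groups:
        u = basis[g.direction] if g.direction is not None else None
        for w in g.words:
            if w in entries:
                continue
            if config.mode == "exact-geometry":
                if u is None:
                    raise ValueError(f"exact-geometry mode requires a direction for word {w!r}")
                vec = u.copy()
            else:
                vec = rng.standard_normal(config.dim)
                if u is not None:
                    vec = vec + config.beta * u
                vec = vec / np.linalg.norm(vec)
            entries[w] = vec
    return SynthTable(dim=config.dim, entries=entries, name=f"synth-beta{config.beta}", config=config)


def _default_direction_map(ds: BenchmarkDataset) -> dict[str, int]:
    """Targets get directions 0/1; attribute groups align with them.

    With two groups, group i shares target i's direction (planted contrast);
    with three or more, groups 0 and 1 align with the targets and later
    groups get fresh directions.
    """
    dmap = {ds.targets[0].label: 0, ds.targets[1].label: 1}
    for i, g in enumerate(ds.attribute_groups):
        dmap[g.label] = i
    return dmap


def table_for_benchmark(
    ds: BenchmarkDataset,
    beta: float,
    seed: int = 0,
    dim: int = 50,
    extra_words: Sequence[str] = (),
    mode: Literal["random", "exact-geometry"] = "random",
    direction_map: dict[str, int | None] | None = None,
    split_hyphens: bool = False,
) -> SynthTable:
    """A token-level synthetic table covering every token of a benchmark.

    Tokens inherit their set's latent direction; tokens shared between sets
    with different directions become neutral (no planted direction), as do
    ``extra_words`` (e.g. the noise lexicon).
    """
    dmap = _default_direction_map(ds) if direction_map is None else dict(direction_map)
    token_dir: dict[str, int | None] = {}
    for s in [*ds.targets, *ds.attribute_groups]:
        direction = dmap.get(s.label)
        for term in s.terms:
            for tok in term_tokens(term, split_hyphens=split_hyphens):
                if tok in token_dir and token_dir[tok] != direction:
                    token_dir[tok] = None  # contested token: neutral
                else:
                    token_dir.setdefault(tok, direction)
    for w in extra_words:
        token_dir.setdefault(w, None)
    by_dir: dict[int | None, list[str]] = {}
    for tok, direction in token_dir.items():
        by_dir.setdefault(direction, []).append(tok)
    groups = [
        SynthGroup(label=f"dir{d}" if d is not None else "neutral", words=words, direction=d)
        for d, words in sorted(by_dir.items(), key=lambda kv: (kv[0] is None, kv[0] or 0))
    ]
    return generate_table(SynthConfig(groups=groups, dim=dim, beta=beta, seed=seed, mode=mode))


def make_synthetic_benchmark(
    n_targets: int = 3,
    n_attributes_per_group: int = 4,
    n_groups: int = 2,
    name: str = "SYN",
) -> BenchmarkDataset:
    """A single-token benchmark shaped like the bundled ones, for simulations."""
    targets = [
        TargetSet("T1", [f"cond1-{i}" for i in range(n_targets)]),
        TargetSet("T2", [f"cond2-{i}" for i in range(n_targets)]),
    ]
    groups = [
        AttributeGroup(f"grp{g + 1}", [f"attr{g + 1}-{i}" for i in range(n_attributes_per_group)])
        for g in range(n_groups)
    ]
    return BenchmarkDataset(name, "synthetic simulation benchmark", targets, groups).check()


def calibration_experiment(
    betas: Sequence[float],
    reps: int = 100,
    dim: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    statistics: Sequence[str] = ("weat", "sdweat"),
    n_targets: int = 3,
    n_attributes_per_group: int = 4,
    sdweat_config: SdweatConfig | None = None,
) -> pd.DataFrame:
    """Operating characteristics of the statistics over a planted-bias grid.

    For each beta, ``reps`` independent tables are generated and each
    requested statistic is run once; the result has one row per
    (beta, statistic) with the rejection rate at ``alpha``, mean score and
    score SD.  Deterministic given ``seed``.
    """
    import logging

    if reps < 50:
        logging.getLogger(__name__).warning("reps=%d < 50: estimates will be noisy", reps)
    ds = make_synthetic_benchmark(n_targets, n_attributes_per_group)
    base_sdconf = sdweat_config or SdweatConfig(n_tests=50, pvalue_replicates=199)
    rows = []
    for beta in betas:
        cells: dict[str, list[tuple[float, float]]] = {s: [] for s in statistics}
        for rep in range(reps):
            # seed depends on rep only: common random numbers across the
            # beta grid, so grid means are directly comparable
            table_seed = seed * 1_000_003 + rep * 7919
            table = table_for_benchmark(ds, beta=beta, seed=table_seed, dim=dim)
            if "weat" in statistics:
                res = run_weat(ds, table, config=WeatConfig(mode="exhaustive"))
                cells["weat"].append((abs(res.effect_size), res.p_value))
            if "sdweat" in statistics:
                from dataclasses import replace

                sres = run_sdweat(ds, table, config=replace(base_sdconf, seed=table_seed + 1))
                cells["sdweat"].append((sres.score, sres.p_value))
        for stat in statistics:
            scores = np.array([c[0] for c in cells[stat]])
            pvals = np.array(
                [np.nan if c[1] is None else c[1] for c in cells[stat]], dtype=float
            )
            rejection = float(np.mean(pvals < alpha)) if not np.isnan(pvals).all() else float("nan")
            rows.append(
                dict(
                    beta=beta,
                    statistic=stat,
                    reps=reps,
                    rejection_rate=rejection,
                    mean_score=float(scores.mean()),
                    sd_score=float(scores.std(ddof=1)) if reps > 1 else 0.0,
                )
            )
    return pd.DataFrame(rows)
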