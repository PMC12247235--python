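"""SD-of-effect-sizes bias statistic over pooled attribute words.

All attribute groups of a benchmark are pooled into one word list.  K small
tests are then constructed by drawing four distinct pooled words per test —
the first two form attribute set A, the last two attribute set B — and the
effect size of each test against the fixed target sets is computed.  The
bias score is the population standard deviation of those K effect sizes:
draws that contrast demographic groups give large effects, mixed draws give
small ones, so a genuinely biased space produces a wide spread.

Because the attribute pool is drawn from as a single list, the statistic
handles any number of labeled demographic groups (multi-class benchmarks)
without choosing a binary split.

The p-value uses a target-shuffle null: target-set membership is repeatedly
re-partitioned (preserving set sizes), the K-draw score recomputed with
fresh attribute draws, and the add-one-corrected exceedance proportion
reported.  The method is pluggable (``pvalue_method``) so an alternative
formula can be swapped in without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .benchmarks import BenchmarkDataset, Term
from .embeddings import BenchmarkPolicy, EmbeddingTable, EmbedPolicy, embed_terms
from .errors import DegenerateDrawsError, OOVError, PoolTooSmallError
from .weat import SdKind, cosine_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SdweatConfig",
    "SdweatResult",
    "pool_attributes",
    "sample_attribute_pairs",
    "sd_of_effect_sizes",
    "run_sdweat",
    "sdweat_pvalue",
]


@dataclass(frozen=True)
class SdweatConfig:
    """Knobs of the SD statistic.

    ``n_tests`` (K) defaults to 100; ``words_per_attribute_set`` is 2 in the
    canonical form (each draw pulls ``2 x words_per_attribute_set`` distinct
    pooled words); larger sets are permitted for sensitivity studies only.
    """

    n_tests: int = 100
    words_per_attribute_set: int = 2
    seed: int = 0
    pvalue_replicates: int = 1000
    pvalue_method: Literal["target-shuffle", "none"] = "target-shuffle"
    sd: SdKind = "population"
    retry_factor: int = 10

    @property
    def words_per_draw(self) -> int:
        return 2 * self.words_per_attribute_set

    def __post_init__(self) -> None:
        if self.n_tests < 2:
            raise ValueError("n_tests must be >= 2")
        if self.words_per_attribute_set < 1:
            raise ValueError("words_per_attribute_set must be >= 1")


@dataclass
class SdweatResult:
    score: float
    effect_sizes: np.ndarray
    p_value: float | None
    draws: list[tuple[tuple[Term, ...], tuple[Term, ...]]]
    config: SdweatConfig
    benchmark: str = ""

    def to_dict(self) -> dict:
        return dict(
            benchmark=self.benchmark,
            score=self.score,
            p_value=self.p_value,
            n_tests=self.config.n_tests,
            seed=self.config.seed,
            effect_sizes=[float(d) for d in self.effect_sizes],
            draws=[{"A": list(a), "B": list(b)} for a, b in self.draws],
        )


def pool_attributes(ds: BenchmarkDataset) -> list[Term]:
    """Concatenate all attribute groups, in declaration order, no dedup."""
    pool: list[Term] = []
    for g in ds.attribute_groups:
        pool.extend(g.terms)
    return pool


def sample_attribute_pairs(
    pool: Sequence[Term], config: SdweatConfig
) -> list[tuple[tuple[Term, ...], tuple[Term, ...]]]:
    """K independent draws of ``2m`` distinct pooled words, split m/m into (A, B)."""
    idx = _draw_indices(
        np.random.default_rng(config.seed), len(pool), config.n_tests, config.words_per_draw
    )
    m = config.words_per_attribute_set
    return [
        (tuple(pool[j] for j in row[:m]), tuple(pool[j] for j in row[m:]))
        for row in idx
    ]


def sd_of_effect_sizes(effect_sizes: Sequence[float], sd: SdKind = "population") -> float:
    """The score itself: standard deviation of the per-draw effect sizes."""
    values = np.asarray(effect_sizes, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 effect sizes")
    return float(np.std(values, ddof=0 if sd == "population" else 1))


# ---------------------------------------------------------------------------
# vectorized internals (cross-checked against the per-draw route in tests)


def _draw_indices(rng: np.random.Generator, pool_size: int, k: int, per_draw: int) -> np.ndarray:
    """(k, per_draw) index rows, each row distinct indices without replacement."""
    if pool_size < per_draw:
        raise PoolTooSmallError(
            f"pool-too-small: {pool_size} pooled words, draw needs {per_draw}"
        )
    return np.argsort(rng.random((k, pool_size)), axis=1)[:, :per_draw]


def _effect_sizes_for_draws(
    cosmat: np.ndarray, x_idx: np.ndarray, y_idx: np.ndarray, draws: np.ndarray, sd: SdKind
) -> tuple[np.ndarray, np.ndarray]:
    """Effect size per draw from a precomputed target x pool cosine matrix.

    Returns ``(d, sigma)`` where sigma is the association SD per draw; a zero
    sigma marks a degenerate draw (d is NaN there).
    """
    m = draws.shape[1] // 2
    s = cosmat[:, draws[:, :m]].mean(axis=2) - cosmat[:, draws[:, m:]].mean(axis=2)
    ddof = 0 if sd == "population" else 1
    sigma = s.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (s[x_idx].mean(axis=0) - s[y_idx].mean(axis=0)) / sigma
    return d, sigma


def _sample_effect_sizes(
    cosmat: np.ndarray,
    x_idx: np.ndarray,
    y_idx: np.ndarray,
    rng: np.random.Generator,
    config: SdweatConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw K attribute pairs and their effect sizes, resampling degenerates."""
    pool_size = cosmat.shape[1]
    draws = _draw_indices(rng, pool_size, config.n_tests, config.words_per_draw)
    d, sigma = _effect_sizes_for_draws(cosmat, x_idx, y_idx, draws, config.sd)
    retries = 0
    cap = config.retry_factor * config.n_tests
    while np.any(sigma == 0):
        bad = np.flatnonzero(sigma == 0)
        retries += bad.size
        if retries > cap:
            raise DegenerateDrawsError(
                f"degenerate-draws: exceeded {cap} resamples of zero-variance attribute draws"
            )
        logger.debug("resampling %d degenerate attribute draws", bad.size)
        draws[bad] = _draw_indices(rng, pool_size, bad.size, config.words_per_draw)
        d, sigma = _effect_sizes_for_draws(cosmat, x_idx, y_idx, draws, config.sd)
    return d, draws


def _embed_matrix(terms, table, policy, what):
    embedded = embed_terms(terms, table, policy)
    if not embedded:
        raise OOVError(what, f"every term of {what} is out of vocabulary")
    return list(embedded), np.array(list(embedded.values()))


def _prepare(ds, table, policy):
    policy = policy if policy is not None else BenchmarkPolicy()
    tgt_policy = policy.target if isinstance(policy, BenchmarkPolicy) else policy
    att_policy = policy.attribute if isinstance(policy, BenchmarkPolicy) else policy
    if att_policy.oov != "error":
        att_policy = replace(att_policy, oov="error")
    _, X = _embed_matrix(ds.targets[0].terms, table, tgt_policy, ds.targets[0].label)
    _, Y = _embed_matrix(ds.targets[1].terms, table, tgt_policy, ds.targets[1].label)
    pool = pool_attributes(ds)
    pool_kept, P = _embed_matrix(pool, table, att_policy, "pooled attributes")
    cosmat = cosine_matrix(np.vstack([X, Y]), P)
    x_idx = np.arange(X.shape[0])
    y_idx = np.arange(X.shape[0], X.shape[0] + Y.shape[0])
    return cosmat, x_idx, y_idx, pool_kept


def run_sdweat(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    config: SdweatConfig | None = None,
) -> SdweatResult:
    """Pool attributes, draw K tests, score = SD of their effect sizes.

    Attribute terms must all embed (OOV is an error for the pool); target
    terms follow the given policy.  Fully deterministic for a fixed seed.
    """
    config = config or SdweatConfig()
    cosmat, x_idx, y_idx, pool = _prepare(ds, table, policy)
    rng = np.random.default_rng(config.seed)
    d, draws = _sample_effect_sizes(cosmat, x_idx, y_idx, rng, config)
    score = sd_of_effect_sizes(d, config.sd)
    p = None
    if config.pvalue_method == "target-shuffle":
        p = _target_shuffle_pvalue(cosmat, x_idx, y_idx, score, rng, config)
    m = config.words_per_attribute_set
    term_draws = [
        (tuple(pool[j] for j in row[:m]), tuple(pool[j] for j in row[m:])) for row in draws
    ]
    return SdweatResult(
        score=score, effect_sizes=d, p_value=p, draws=term_draws, config=config, benchmark=ds.name
    )


def _target_shuffle_pvalue(cosmat, x_idx, y_idx, score_obs, rng, config) -> float:
    r = config.pvalue_replicates
    if r < 99:
        raise ValueError("pvalue_replicates must be >= 99")
    n_targets = cosmat.shape[0]
    nx = x_idx.size
    exceed = 0
    for _ in range(r):
        perm = rng.permutation(n_targets)
        d_null, _ = _sample_effect_sizes(cosmat, perm[:nx], perm[nx:], rng, config)
        if sd_of_effect_sizes(d_null, config.sd) >= score_obs:
            exceed += 1
    return (exceed + 1) / (r + 1)


def sdweat_pvalue(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    config: SdweatConfig | None = None,
) -> float:
    """Standalone target-shuffle p-value (same null as :func:`run_sdweat`)."""
    config = config or SdweatConfig()
    if config.pvalue_method != "target-shuffle":
        raise ValueError("sdweat_pvalue requires pvalue_method='target-shuffle'")
    result = run_sdweat(ds, table, policy, config)
    assert result.p_value is not None
    return result.p_value
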