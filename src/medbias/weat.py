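"""Association-test statistics over word-embedding vectors.

The test compares two target vector sets X, Y against two attribute vector
sets A, B:

* per-word association ``s(w, A, B) = mean_a cos(w, a) - mean_b cos(w, b)``;
* test statistic ``S = sum_x s(x) - sum_y s(y)``;
* effect size ``d = (mean_x s(x) - mean_y s(y)) / sd_{w in X+Y} s(w)`` with
  the population (divide-by-N) standard deviation, which bounds ``|d| <= 2``
  for equal-size target sets;
* a one-sided permutation p-value over equal-size re-partitions of X+Y,
  ``p = Pr[S(X', Y') > S(X, Y)]`` with strict inequality and no smoothing.

Small instances are enumerated exhaustively; larger ones fall back to
seeded Monte-Carlo sampling of partitions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .benchmarks import BenchmarkDataset
from .embeddings import BenchmarkPolicy, EmbeddingTable, EmbedPolicy, embed_terms
from .errors import DegenerateEmbeddingError, OOVError, ZeroVarianceError

__all__ = [
    "WeatInputs",
    "WeatConfig",
    "WeatResult",
    "cosine",
    "association",
    "association_profile",
    "weat_statistic",
    "effect_size",
    "permutation_p",
    "run_weat",
    "pairwise_weat",
]

SdKind = Literal["population", "sample"]


def _as_matrix(vectors: Sequence, what: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(vectors, dtype=float))
    if mat.size == 0 or mat.shape[0] == 0:
        raise ValueError(f"{what} is empty")
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise DegenerateEmbeddingError(f"degenerate-embedding: zero-norm vector in {what}")
    return mat


@dataclass
class WeatInputs:
    """Target (X, Y) and attribute (A, B) vector sets plus provenance labels."""

    X: np.ndarray
    Y: np.ndarray
    A: np.ndarray
    B: np.ndarray
    x_label: str = "X"
    y_label: str = "Y"
    a_label: str = "A"
    b_label: str = "B"

    def __post_init__(self) -> None:
        self.X = _as_matrix(self.X, "X")
        self.Y = _as_matrix(self.Y, "Y")
        self.A = _as_matrix(self.A, "A")
        self.B = _as_matrix(self.B, "B")
        dims = {m.shape[1] for m in (self.X, self.Y, self.A, self.B)}
        if len(dims) != 1:
            raise ValueError(f"vector sets mix dimensions: {sorted(dims)}")

    @property
    def balanced(self) -> bool:
        return self.X.shape[0] == self.Y.shape[0]

    def swapped_targets(self) -> "WeatInputs":
        return WeatInputs(self.Y, self.X, self.A, self.B, self.y_label, self.x_label, self.a_label, self.b_label)

    def swapped_attributes(self) -> "WeatInputs":
        return WeatInputs(self.X, self.Y, self.B, self.A, self.x_label, self.y_label, self.b_label, self.a_label)


@dataclass(frozen=True)
class WeatConfig:
    mode: Literal["auto", "exhaustive", "monte-carlo"] = "auto"
    n_draws: int = 10_000
    max_exhaustive: int = 200_000
    seed: int | None = None
    sd: SdKind = "population"


@dataclass
class WeatResult:
    """Effect size, statistic and permutation p with full provenance."""

    effect_size: float
    statistic: float
    p_value: float
    n_permutations: int
    mode: str
    seed: int | None
    tie_fraction: float
    benchmark: str = ""
    x_label: str = "X"
    y_label: str = "Y"
    a_label: str = "A"
    b_label: str = "B"

    def to_dict(self) -> dict:
        return dict(
            benchmark=self.benchmark,
            pair=f"{self.a_label},{self.b_label}",
            effect_size=self.effect_size,
            statistic=self.statistic,
            p_value=self.p_value,
            n_permutations=self.n_permutations,
            mode=self.mode,
            seed=self.seed,
            tie_fraction=self.tie_fraction,
        )


# ---------------------------------------------------------------------------
# core statistics


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity in [-1, 1]; zero-norm inputs are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateEmbeddingError("degenerate-embedding: cosine of zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_matrix(W: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities, shape (len(W), len(V))."""
    W = _as_matrix(W, "W")
    V = _as_matrix(V, "V")
    Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
    Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
    return Wn @ Vn.T


def association(w: Sequence[float], A: Sequence, B: Sequence) -> float:
    """s(w, A, B): mean cosine of w to A minus mean cosine of w to B."""
    w = np.asarray(w, dtype=float)
    s = cosine_matrix(w[None, :], np.asarray(A, dtype=float)).mean() - cosine_matrix(
        w[None, :], np.asarray(B, dtype=float)
    ).mean()
    return float(s)


def association_profile(inputs: WeatInputs) -> tuple[np.ndarray, np.ndarray]:
    """Vectors of s(x, A, B) over X and s(y, A, B) over Y."""
    sx = cosine_matrix(inputs.X, inputs.A).mean(axis=1) - cosine_matrix(inputs.X, inputs.B).mean(axis=1)
    sy = cosine_matrix(inputs.Y, inputs.A).mean(axis=1) - cosine_matrix(inputs.Y, inputs.B).mean(axis=1)
    return sx, sy


def weat_statistic(inputs: WeatInputs) -> float:
    """S(X, Y, A, B) = sum of target-1 associations minus target-2 associations."""
    sx, sy = association_profile(inputs)
    return float(sx.sum() - sy.sum())


def _sd(values: np.ndarray, kind: SdKind) -> float:
    ddof = 0 if kind == "population" else 1
    return float(np.std(values, ddof=ddof))


def effect_size(inputs: WeatInputs, sd: SdKind = "population") -> float:
    """Standardized mean association difference; |d| <= 2 for balanced targets."""
    sx, sy = association_profile(inputs)
    sigma = _sd(np.concatenate([sx, sy]), sd)
    if sigma == 0:
        raise ZeroVarianceError("zero-variance-association: all association scores are equal")
    return float((sx.mean() - sy.mean()) / sigma)


def permutation_p(
    inputs: WeatInputs,
    mode: Literal["auto", "exhaustive", "monte-carlo"] = "auto",
    n_draws: int = 10_000,
    seed: int | None = None,
    max_exhaustive: int = 200_000,
) -> tuple[float, int, str, float]:
    """One-sided permutation p-value over equal-size partitions of X+Y.

    Returns ``(p, n_partitions_used, mode_used, tie_fraction)``.  Exhaustive
    mode enumerates all C(2n, n) assignments of the pooled targets when that
    count is at most ``max_exhaustive``; Monte-Carlo draws seeded uniform
    partitions and reports the raw (unsmoothed) exceedance proportion.
    """
    if not inputs.balanced:
        raise ValueError("permutation test requires |X| == |Y|")
    n = inputs.X.shape[0]
    s_all = np.concatenate(association_profile(inputs))  # X rows first, then Y
    total = s_all.sum()
    # same arithmetic pathway as the enumerated partitions, so the identity
    # partition ties S_obs exactly instead of drifting by an ulp
    s_obs = 2.0 * s_all[:n].sum() - total
    n_total = 2 * n
    n_exhaustive = math.comb(n_total, n)
    if mode == "auto":
        mode = "exhaustive" if n_exhaustive <= max_exhaustive else "monte-carlo"
    if mode == "exhaustive":
        greater = ties = 0
        for combo in itertools.combinations(range(n_total), n):
            s_part = 2.0 * s_all[list(combo)].sum() - total
            if s_part > s_obs:
                greater += 1
            elif s_part == s_obs:
                ties += 1
        return greater / n_exhaustive, n_exhaustive, "exhaustive", ties / n_exhaustive
    if mode == "monte-carlo":
        if n_draws < 100:
            raise ValueError("monte-carlo mode requires n_draws >= 100")
        rng = np.random.default_rng(seed)
        greater = ties = 0
        for _ in range(n_draws):
            idx = rng.permutation(n_total)[:n]
            s_part = 2.0 * s_all[idx].sum() - total
            if s_part > s_obs:
                greater += 1
            elif s_part == s_obs:
                ties += 1
        return greater / n_draws, n_draws, "monte-carlo", ties / n_draws
    raise ValueError(f"unknown permutation mode {mode!r}")


def evaluate(inputs: WeatInputs, config: WeatConfig | None = None, benchmark: str = "") -> WeatResult:
    """Compute effect size, statistic and p-value for assembled inputs."""
    config = config or WeatConfig()
    d = effect_size(inputs, sd=config.sd)
    s = weat_statistic(inputs)
    p, n_used, mode_used, ties = permutation_p(
        inputs,
        mode=config.mode,
        n_draws=config.n_draws,
        seed=config.seed,
        max_exhaustive=config.max_exhaustive,
    )
    return WeatResult(
        effect_size=d,
        statistic=s,
        p_value=p,
        n_permutations=n_used,
        mode=mode_used,
        seed=config.seed,
        tie_fraction=ties,
        benchmark=benchmark,
        x_label=inputs.x_label,
        y_label=inputs.y_label,
        a_label=inputs.a_label,
        b_label=inputs.b_label,
    )


# ---------------------------------------------------------------------------
# benchmark-level entry points


def build_inputs(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    group_pair: tuple[str, str] | None = None,
) -> WeatInputs:
    """Embed a benchmark's targets and one ordered attribute-group pair."""
    policy = policy if policy is not None else BenchmarkPolicy()
    tgt_policy = policy.target if isinstance(policy, BenchmarkPolicy) else policy
    att_policy = policy.attribute if isinstance(policy, BenchmarkPolicy) else policy
    if group_pair is None:
        if len(ds.attribute_groups) < 2:
            raise ValueError("benchmark has fewer than two attribute groups; name a pair explicitly")
        group_pair = (ds.attribute_groups[0].label, ds.attribute_groups[1].label)
    ga = ds.attribute_group(group_pair[0])
    gb = ds.attribute_group(group_pair[1])

    def _vectors(terms, pol, what):
        embedded = embed_terms(terms, table, pol)
        if not embedded:
            raise OOVError(what, f"every term of {what} is out of vocabulary")
        return np.array(list(embedded.values()))

    return WeatInputs(
        X=_vectors(ds.targets[0].terms, tgt_policy, ds.targets[0].label),
        Y=_vectors(ds.targets[1].terms, tgt_policy, ds.targets[1].label),
        A=_vectors(ga.terms, att_policy, ga.label),
        B=_vectors(gb.terms, att_policy, gb.label),
        x_label=ds.targets[0].label,
        y_label=ds.targets[1].label,
        a_label=ga.label,
        b_label=gb.label,
    )


def run_weat(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    group_pair: tuple[str, str] | None = None,
    config: WeatConfig | None = None,
) -> WeatResult:
    """Full pipeline: embed the benchmark, assemble inputs, evaluate."""
    inputs = build_inputs(ds, table, policy, group_pair)
    return evaluate(inputs, config, benchmark=ds.name)


def pairwise_weat(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    config: WeatConfig | None = None,
) -> list[WeatResult]:
    """Binary tests over every ordered pair of distinct attribute groups."""
    labels = [g.label for g in ds.attribute_groups]
    if len(labels) < 2:
        raise ValueError("pairwise analysis needs at least two labeled attribute groups")
    return [
        run_weat(ds, table, policy, group_pair=(a, b), config=config)
        for a, b in itertools.permutations(labels, 2)
    ]
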