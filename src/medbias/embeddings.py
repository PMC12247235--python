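"""Word-vector tables and per-term embedding with mean pooling.

Static tables are read from the two standard plain-text dialects:

* ``glove-text`` — one ``token v1 ... vD`` line per entry, no header;
* ``word2vec-text`` — identical rows preceded by a ``count dim`` header.

A term maps to one vector: single tokens look up directly, multi-word terms
average their per-token vectors (mean pooling), mirroring how sub-word token
vectors of contextual models are averaged into one term vector.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Protocol

import numpy as np

from .benchmarks import BenchmarkDataset, Term, term_tokens
from .errors import DegenerateEmbeddingError, OOVError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingTable",
    "EmbedPolicy",
    "ContextualBackend",
    "load_word_vectors",
    "save_word_vectors",
    "embed_term",
    "embed_benchmark",
    "pool_subword_vectors",
]


@dataclass
class EmbeddingTable:
    """Mapping from tokens to fixed-dimension real vectors."""

    dim: int
    entries: dict[str, np.ndarray]
    name: str = ""

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if not self.entries:
            raise ValueError("embedding table has no entries")
        for tok, vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {vec.shape}, expected ({self.dim},)")
            if not np.any(vec):
                raise DegenerateEmbeddingError(f"all-zero vector for token {tok!r}")
            self.entries[tok] = vec

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def vocab(self) -> set[str]:
        return set(self.entries)

    def lookup(self, token: str, case: str = "exact-then-lower") -> np.ndarray | None:
        if token in self.entries:
            return self.entries[token]
        if case == "exact-then-lower" and token.lower() in self.entries:
            logger.debug("token %r resolved via lowercase fallback", token)
            return self.entries[token.lower()]
        return None


@dataclass(frozen=True)
class EmbedPolicy:
    """How terms are turned into vectors.

    ``oov`` applies when a token has no vector: ``error`` raises, ``skip``
    omits the whole term (callers receive a smaller mapping).  Multi-word
    handling is always mean-of-token-vectors; ``split_hyphens`` optionally
    treats hyphens as token separators.
    """

    oov: Literal["error", "skip"] = "error"
    case: Literal["exact", "exact-then-lower"] = "exact-then-lower"
    split_hyphens: bool = False

    def __post_init__(self) -> None:
        if self.oov not in ("error", "skip"):
            raise ValueError(f"invalid oov policy {self.oov!r}")
        if self.case not in ("exact", "exact-then-lower"):
            raise ValueError(f"invalid case policy {self.case!r}")


class ContextualBackend(Protocol):
    """Contract for model-backed embedders: term -> list of sub-word vectors.

    Implementations wrap external models (and must be deterministic for a
    fixed term).  The core only ever mean-pools whatever comes back; no model
    library is imported here.
    """

    def subword_vectors(self, term: str) -> list[np.ndarray]: ...


def pool_subword_vectors(vectors: Iterable[np.ndarray]) -> np.ndarray:
    """Mean-pool sub-word vectors into one term vector."""
    mat = np.asarray(list(vectors), dtype=float)
    if mat.size == 0:
        raise ValueError("no sub-word vectors to pool")
    return mat.mean(axis=0)


# ---------------------------------------------------------------------------
# text-format I/O


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return path.open("r", encoding="utf-8")


def load_word_vectors(
    path: str | Path,
    dialect: Literal["glove-text", "word2vec-text"] = "glove-text",
    name: str | None = None,
) -> EmbeddingTable:
    """Load a plain-text word-vector table (optionally gzip-compressed).

    Duplicate tokens keep the last occurrence (with a logged warning).
    """
    path = Path(path)
    entries: dict[str, np.ndarray] = {}
    dim: int | None = None
    declared: tuple[int, int] | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(" ")
            if dialect == "word2vec-text" and lineno == 1:
                if len(parts) != 2:
                    raise ParseError("expected 'count dim' header", path=path, line=lineno)
                try:
                    declared = (int(parts[0]), int(parts[1]))
                except ValueError as exc:
                    raise ParseError("non-integer header", path=path, line=lineno) from exc
                dim = declared[1]
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise ParseError("row has no vector components", path=path, line=lineno)
            if len(values) != dim:
                raise ParseError(
                    f"row for {token!r} has {len(values)} components, expected {dim}",
                    path=path,
                    line=lineno,
                )
            try:
                vec = np.array(values, dtype=float)
            except ValueError as exc:
                raise ParseError(f"non-numeric component in row for {token!r}", path=path, line=lineno) from exc
            if token in entries:
                logger.warning("duplicate token %r at line %d: last occurrence wins", token, lineno)
            entries[token] = vec
    if not entries:
        raise ParseError("empty word-vector file", path=path)
    if declared is not None and declared[0] != len(entries):
        logger.warning(
            "header declares %d entries but %d were read", declared[0], len(entries)
        )
    return EmbeddingTable(dim=int(dim), entries=entries, name=name or path.stem)


def save_word_vectors(
    table: EmbeddingTable,
    path: str | Path,
    dialect: Literal["glove-text", "word2vec-text"] = "glove-text",
    fmt: str = "%.8g",
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "word2vec-text":
            fh.write(f"{len(table)} {table.dim}\n")
        for token, vec in table.entries.items():
            fh.write(token + " " + " ".join(fmt % v for v in vec) + "\n")


# ---------------------------------------------------------------------------
# term embedding


def embed_term(term: Term, table: EmbeddingTable, policy: EmbedPolicy | None = None) -> np.ndarray:
    """One vector per term: direct lookup, or mean over whitespace tokens.

    Raises :class:`OOVError` for missing tokens (policy ``error``) and
    :class:`DegenerateEmbeddingError` if pooling yields a zero vector.
    """
    policy = policy or EmbedPolicy()
    if not term or not term.strip():
        raise ValueError("empty term")
    tokens = term_tokens(term, split_hyphens=policy.split_hyphens)
    vectors = []
    for tok in tokens:
        vec = table.lookup(tok, case=policy.case)
        if vec is None:
            raise OOVError(tok, term)
        vectors.append(vec)
    pooled = pool_subword_vectors(vectors)
    if not np.any(pooled):
        raise DegenerateEmbeddingError(f"degenerate-embedding: term {term!r} pooled to the zero vector")
    return pooled


def embed_terms(
    terms: Iterable[Term],
    table: EmbeddingTable,
    policy: EmbedPolicy | None = None,
    *,
    on_skip: Callable[[Term], None] | None = None,
) -> dict[Term, np.ndarray]:
    """Embed many terms, honoring the OOV policy (skip drops the term)."""
    policy = policy or EmbedPolicy()
    out: dict[Term, np.ndarray] = {}
    for term in terms:
        try:
            out[term] = embed_term(term, table, policy)
        except OOVError:
            if policy.oov == "error":
                raise
            logger.warning("skipping out-of-vocabulary term %r", term)
            if on_skip is not None:
                on_skip(term)
    return out


@dataclass(frozen=True)
class BenchmarkPolicy:
    """Per-role OOV handling: targets may be skipped, attributes must embed."""

    target: EmbedPolicy = field(default_factory=lambda: EmbedPolicy(oov="skip"))
    attribute: EmbedPolicy = field(default_factory=lambda: EmbedPolicy(oov="error"))


def embed_benchmark(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: EmbedPolicy | BenchmarkPolicy | None = None,
) -> dict[Term, np.ndarray]:
    """Embed every term of every set of a benchmark.

    Returns a term -> vector mapping.  With a skip policy, a set that loses
    all of its terms is an error.
    """
    if policy is None:
        policy = EmbedPolicy()
    tgt_policy = policy.target if isinstance(policy, BenchmarkPolicy) else policy
    att_policy = policy.attribute if isinstance(policy, BenchmarkPolicy) else policy
    out: dict[Term, np.ndarray] = {}
    for s in ds.targets:
        embedded = embed_terms(s.terms, table, tgt_policy)
        if not embedded:
            raise OOVError(s.label, f"every term of target set {s.label!r} is out of vocabulary")
        out.update(embedded)
    for g in ds.attribute_groups:
        embedded = embed_terms(g.terms, table, att_policy)
        if not embedded:
            raise OOVError(g.label, f"every term of attribute group {g.label!r} is out of vocabulary")
        out.update(embedded)
    return out
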