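"""Attribute-word importance: which pooled words drive the effect sizes.

The pooled attribute list is augmented with sixteen inanimate-object noise
words, many small tests are drawn exactly as in the SD statistic, and each
word is credited with the mean effect size of the tests in which it landed
in a given attribute slot: slot A tests measure its pull toward target set
1, slot B tests toward target set 2.  Words that never occupied a slot keep
a missing cell (never zero-filled), with occupancy counts reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkDataset, Term
from .embeddings import BenchmarkPolicy, EmbeddingTable, EmbedPolicy
from .sdweat import SdweatConfig, _prepare, _sample_effect_sizes, pool_attributes

__all__ = [
    "NOISE_LEXICON",
    "ImportanceMatrix",
    "augment_pool",
    "run_importance",
    "export_importance",
    "read_importance",
    "concat_importance",
]

# The sixteen inanimate-object noise words, in canonical order.
NOISE_LEXICON: tuple[str, ...] = (
    "rock", "dirt", "sand", "clay",
    "sky", "cloud", "water", "air",
    "car", "bicycle", "train", "plane",
    "pen", "paper", "book", "laptop",
)


@dataclass
class ImportanceMatrix:
    """Word x target-slot matrix of mean effect sizes plus occupancy counts.

    ``values`` holds NaN where a word never occupied the slot; ``counts``
    holds the per-cell occupancy.  A cell is defined iff its count > 0.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    n_tests: int

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.counts.index) or not self.values.columns.equals(
            self.counts.columns
        ):
            raise ValueError("values and counts must share index and columns")

    @property
    def words(self) -> list[str]:
        return list(self.values.index)


def augment_pool(pool: Sequence[Term], lexicon: Sequence[str] = NOISE_LEXICON) -> list[Term]:
    """Append the noise lexicon to the pooled attribute list."""
    overlap = set(pool) & set(lexicon)
    if overlap:
        raise ValueError(f"noise lexicon overlaps the attribute pool: {sorted(overlap)}")
    return list(pool) + list(lexicon)


def run_importance(
    ds: BenchmarkDataset,
    table: EmbeddingTable,
    policy: BenchmarkPolicy | EmbedPolicy | None = None,
    n_tests: int = 500,
    seed: int = 0,
    lexicon: Sequence[str] | None = NOISE_LEXICON,
    words_per_attribute_set: int = 2,
) -> ImportanceMatrix:
    """Run ``n_tests`` pooled-attribute draws and attribute effects per slot.

    For each test the drawn pair (A, B) and its effect size d are recorded;
    a word in slot A contributes d to its Target-1 cell, a word in slot B
    contributes d to its Target-2 cell.  Cells are means over contributions.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    augmented = ds
    if lexicon:
        pooled = pool_attributes(ds)
        augment_pool(pooled, lexicon)  # raises on overlap
        from .benchmarks import AttributeGroup

        augmented = BenchmarkDataset(
            name=ds.name,
            description=ds.description,
            targets=ds.targets,
            attribute_groups=[*ds.attribute_groups, AttributeGroup("noise", list(lexicon))],
            references=ds.references,
        )
    config = SdweatConfig(
        n_tests=max(n_tests, 2),
        words_per_attribute_set=words_per_attribute_set,
        seed=seed,
        pvalue_method="none",
    )
    cosmat, x_idx, y_idx, pool = _prepare(augmented, table, policy)
    rng = np.random.default_rng(seed)
    d, draws = _sample_effect_sizes(cosmat, x_idx, y_idx, rng, config)
    d, draws = d[:n_tests], draws[:n_tests]

    m = words_per_attribute_set
    cols = [f"{ds.name}: Target 1", f"{ds.name}: Target 2"]
    sums = np.zeros((len(pool), 2))
    counts = np.zeros((len(pool), 2), dtype=int)
    for t in range(draws.shape[0]):
        for j in draws[t, :m]:
            sums[j, 0] += d[t]
            counts[j, 0] += 1
        for j in draws[t, m:]:
            sums[j, 1] += d[t]
            counts[j, 1] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ImportanceMatrix(
        values=pd.DataFrame(means, index=list(pool), columns=cols),
        counts=pd.DataFrame(counts, index=list(pool), columns=cols),
        n_tests=draws.shape[0],
    )


def concat_importance(matrices: Sequence[ImportanceMatrix]) -> ImportanceMatrix:
    """Join per-benchmark matrices column-wise (outer join on words)."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    values = pd.concat([m.values for m in matrices], axis=1)
    counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(int)
    return ImportanceMatrix(values=values, counts=counts, n_tests=matrices[0].n_tests)


def _counts_path(path: Path) -> Path:
    return path.with_name(path.stem + ".counts" + path.suffix)


def export_importance(
    matrix: ImportanceMatrix, path: str | Path, format: Literal["csv", "json"] = "csv"
) -> None:
    """Write the matrix (CSV: values + parallel ``.counts`` file; JSON: one file)."""
    path = Path(path)
    if format == "csv":
        matrix.values.to_csv(path, index_label="word")
        matrix.counts.to_csv(_counts_path(path), index_label="word")
    elif format == "json":
        doc = {
            "n_tests": matrix.n_tests,
            "columns": list(matrix.values.columns),
            "words": list(matrix.values.index),
            "values": [
                [None if pd.isna(v) else float(v) for v in row]
                for row in matrix.values.to_numpy()
            ],
            "counts": matrix.counts.to_numpy().tolist(),
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_importance(path: str | Path, format: Literal["csv", "json"] = "csv") -> ImportanceMatrix:
    path = Path(path)
    if format == "csv":
        values = pd.read_csv(path, index_col="word").rename_axis(index=None)
        counts = pd.read_csv(_counts_path(path), index_col="word").rename_axis(index=None)
        n_tests = int(counts.to_numpy().sum(axis=0).max() // 2) if counts.size else 0
        return ImportanceMatrix(values=values, counts=counts, n_tests=n_tests)
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        values = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in doc["values"]],
            index=doc["words"],
            columns=doc["columns"],
        )
        counts = pd.DataFrame(doc["counts"], index=doc["words"], columns=doc["columns"])
        return ImportanceMatrix(values=values, counts=counts, n_tests=doc["n_tests"])
    raise ValueError(f"unknown format {format!r}")
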