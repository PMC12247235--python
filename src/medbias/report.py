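"""Suite runner and table-style report writers.

A suite evaluates one statistic for every (embedding source, benchmark)
cell and renders a table whose cells read ``0.727*(0.003)``: score to three
decimals, an asterisk when p < alpha, p-value in parentheses.  Full
precision always goes to the JSON sidecar, along with a manifest (config
echo, seeds, library versions) sufficient to regenerate every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import __version__
from .benchmarks import BenchmarkDataset, FIXTURE_NAMES, load_fixture, read_benchmark
from .embeddings import load_word_vectors
from .errors import MedbiasError
from .sdweat import SdweatConfig, run_sdweat
from .weat import WeatConfig, run_weat

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingSource", "RunConfig", "Cell", "ReportTable", "run_suite", "write_report", "read_report"]


@dataclass(frozen=True)
class EmbeddingSource:
    name: str
    path: str
    dialect: Literal["glove-text", "word2vec-text"] = "glove-text"


@dataclass
class RunConfig:
    benchmarks: list[str]
    embeddings: list[EmbeddingSource]
    statistic: Literal["weat", "sdweat"] = "sdweat"
    n_tests: int = 100
    pvalue_replicates: int = 1000
    seed: int = 0
    alpha: float = 0.05
    group_pair: tuple[str, str] | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data["embeddings"] = [EmbeddingSource(**e) for e in data.get("embeddings", [])]
        if data.get("group_pair") is not None:
            data["group_pair"] = tuple(data["group_pair"])
        return cls(**data)


@dataclass
class Cell:
    score: float | None = None
    p_value: float | None = None
    error: str | None = None

    def starred(self, alpha: float) -> bool:
        return self.p_value is not None and self.p_value < alpha

    def render(self, alpha: float) -> str:
        if self.error is not None:
            return "ERROR"
        assert self.score is not None
        star = "*" if self.starred(alpha) else ""
        if self.p_value is None:
            return f"{self.score:.3f}{star}"
        p = "< 0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"
        return f"{self.score:.3f}{star}({p})"


@dataclass
class ReportTable:
    rows: list[str]
    columns: list[str]
    cells: dict[tuple[str, str], Cell]
    alpha: float = 0.05
    statistic: str = "sdweat"

    @property
    def has_errors(self) -> bool:
        return any(c.error is not None for c in self.cells.values())

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "alpha": self.alpha,
            "rows": self.rows,
            "columns": self.columns,
            "cells": [
                {"row": r, "column": c, **asdict(cell)} for (r, c), cell in sorted(self.cells.items())
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReportTable":
        cells = {
            (c["row"], c["column"]): Cell(c.get("score"), c.get("p_value"), c.get("error"))
            for c in data["cells"]
        }
        return cls(
            rows=list(data["rows"]),
            columns=list(data["columns"]),
            cells=cells,
            alpha=data.get("alpha", 0.05),
            statistic=data.get("statistic", "sdweat"),
        )


def _load_benchmark(spec: str) -> BenchmarkDataset:
    if spec in FIXTURE_NAMES:
        return load_fixture(spec)
    return read_benchmark(spec)


def run_suite(config: RunConfig) -> ReportTable:
    """One cell per (embedding source, benchmark); failures become error cells."""
    datasets = {}
    for spec in config.benchmarks:
        ds = _load_benchmark(spec)
        datasets[ds.name] = ds
    table = ReportTable(
        rows=[e.name for e in config.embeddings],
        columns=list(datasets),
        cells={},
        alpha=config.alpha,
        statistic=config.statistic,
    )
    for source in config.embeddings:
        try:
            emb = load_word_vectors(source.path, source.dialect, name=source.name)
        except (OSError, MedbiasError) as exc:
            for col in table.columns:
                table.cells[(source.name, col)] = Cell(error=str(exc))
            logger.error("embedding source %s failed to load: %s", source.name, exc)
            continue
        for col, ds in datasets.items():
            try:
                if config.statistic == "sdweat":
                    res = run_sdweat(
                        ds,
                        emb,
                        config=SdweatConfig(
                            n_tests=config.n_tests,
                            seed=config.seed,
                            pvalue_replicates=config.pvalue_replicates,
                        ),
                    )
                    cell = Cell(score=res.score, p_value=res.p_value)
                else:
                    res = run_weat(
                        ds, emb, group_pair=config.group_pair, config=WeatConfig(seed=config.seed)
                    )
                    cell = Cell(score=res.effect_size, p_value=res.p_value)
            except (MedbiasError, ValueError) as exc:
                cell = Cell(error=str(exc))
                logger.error("cell (%s, %s) failed: %s", source.name, col, exc)
            table.cells[(source.name, col)] = cell
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(table, out / "report.tsv", "tsv")
        write_report(table, out / "report.json", "json")
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "config": {
                **{k: v for k, v in asdict(config).items() if k != "embeddings"},
                "embeddings": [asdict(e) for e in config.embeddings],
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return table


def write_report(
    table: ReportTable, path: str | Path, format: Literal["tsv", "json", "markdown"] = "tsv"
) -> None:
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(table.to_dict(), indent=2) + "\n", encoding="utf-8")
        return
    header = ["source", *table.columns]
    lines = []
    if format == "tsv":
        lines.append("\t".join(header))
        for row in table.rows:
            lines.append(
                "\t".join([row, *(table.cells[(row, c)].render(table.alpha) for c in table.columns)])
            )
    elif format == "markdown":
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join([" --- "] * len(header)) + "|")
        for row in table.rows:
            cells = [table.cells[(row, c)].render(table.alpha) for c in table.columns]
            lines.append("| " + " | ".join([f"**{row}**", *cells]) + " |")
    else:
        raise ValueError(f"unknown report format {format!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> ReportTable:
    """Read back a JSON report (the full-precision dialect)."""
    return ReportTable.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
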