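"""Benchmark datasets: two target term sets plus labeled attribute groups.

A benchmark couples two target sets (e.g. male-linked and female-linked
medical conditions) with one or more labeled attribute groups (gender terms,
ethnicity terms).  Binary benchmarks carry two attribute groups; multi-class
benchmarks carry three or more groups whose union forms the pooled attribute
list used by the SD-based statistic.

File formats
------------
JSON::

    {"name": ..., "description": ...,
     "targets": [{"label": "T1", "terms": [...]}, {"label": "T2", ...}],
     "attribute_groups": [{"label": ..., "terms": [...]}, ...],
     "references": [...]}

CSV: columns ``set_kind,set_label,term`` where ``set_kind`` is one of
``meta`` (rows ``name``/``description``), ``target``, ``attribute``,
``reference``.  Both dialects are UTF-8 and round-trip exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import BenchmarkValidationError, ParseError

__all__ = [
    "TargetSet",
    "AttributeGroup",
    "BenchmarkDataset",
    "ManifestEntry",
    "MANIFEST",
    "Violation",
    "ValidationReport",
    "FIXTURE_NAMES",
    "read_benchmark",
    "write_benchmark",
    "validate_benchmark",
    "filter_by_vocabulary",
    "load_fixture",
]

Term = str

FIXTURE_NAMES = ("G-1", "G-2", "G-3", "G-4", "E-1", "E-2", "H-1")


def _check_term(text: str) -> str:
    if not isinstance(text, str) or not text.strip():
        raise BenchmarkValidationError(["empty-term"], [f"empty or blank term: {text!r}"])
    if "\n" in text or "\r" in text:
        raise BenchmarkValidationError(["newline-in-term"], [f"term contains newline: {text!r}"])
    return text.strip()


@dataclass
class _TermSet:
    label: str
    terms: list[Term]

    def __post_init__(self) -> None:
        self.terms = [_check_term(t) for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)


class TargetSet(_TermSet):
    """An ordered, duplicate-free list of target terms (one side of X/Y)."""


class AttributeGroup(_TermSet):
    """An ordered, duplicate-free list of attribute terms (one demographic group)."""


@dataclass
class BenchmarkDataset:
    name: str
    description: str
    targets: list[TargetSet]
    attribute_groups: list[AttributeGroup]
    references: list[str] = field(default_factory=list)

    def attribute_group(self, label: str) -> AttributeGroup:
        for g in self.attribute_groups:
            if g.label == label:
                return g
        raise KeyError(f"no attribute group labeled {label!r} in {self.name}")

    @property
    def all_terms(self) -> list[Term]:
        out: list[Term] = []
        for s in [*self.targets, *self.attribute_groups]:
            out.extend(s.terms)
        return out

    def violations(self, *, require_equal_targets: bool = True) -> list["Violation"]:
        """Structural invariant check; returns violations instead of raising."""
        out: list[Violation] = []
        if len(self.targets) != 2:
            out.append(Violation("target-set-count", f"expected 2 target sets, got {len(self.targets)}"))
        for s in [*self.targets, *self.attribute_groups]:
            if not s.terms:
                out.append(Violation("empty-set", f"set {s.label!r} has no terms"))
            dupes = {t for t in s.terms if s.terms.count(t) > 1}
            for t in sorted(dupes):
                out.append(Violation("duplicate-term", f"term {t!r} repeated in set {s.label!r}"))
        if len(self.targets) == 2:
            overlap = set(self.targets[0].terms) & set(self.targets[1].terms)
            for t in sorted(overlap):
                out.append(Violation("overlapping-targets", f"term {t!r} in both target sets"))
            if require_equal_targets and len(self.targets[0]) != len(self.targets[1]):
                out.append(
                    Violation(
                        "unequal-targets",
                        f"target sets differ in size: {len(self.targets[0])} != {len(self.targets[1])}",
                    )
                )
        for i, g in enumerate(self.attribute_groups):
            for h in self.attribute_groups[i + 1 :]:
                for t in sorted(set(g.terms) & set(h.terms)):
                    out.append(
                        Violation("overlapping-groups", f"term {t!r} in groups {g.label!r} and {h.label!r}")
                    )
        return out

    def check(self, *, require_equal_targets: bool = True) -> "BenchmarkDataset":
        """Raise :class:`BenchmarkValidationError` on any invariant violation."""
        v = self.violations(require_equal_targets=require_equal_targets)
        if v:
            raise BenchmarkValidationError([x.code for x in v], [x.message for x in v])
        return self


@dataclass(frozen=True)
class ManifestEntry:
    """Expected shape of one benchmark: term counts per set, pooled or binary."""

    n_target_terms: int
    n_attribute_groups: int
    n_terms_per_group: int
    pooled: bool = False
    pooled_size: int = 0


# Expected shapes of the bundled benchmarks.  Pooled entries record the size
# of the pooled attribute list; the labeled sub-groups (3 x 4) are retained in
# the files so pairwise analysis keeps its group labels.
MANIFEST: dict[str, ManifestEntry] = {
    "G-1": ManifestEntry(6, 2, 8),
    "G-2": ManifestEntry(11, 2, 8),
    "G-3": ManifestEntry(5, 2, 8),
    "G-4": ManifestEntry(10, 2, 8),
    "E-1": ManifestEntry(5, 2, 7),
    "E-2": ManifestEntry(4, 3, 4, pooled=True, pooled_size=12),
    "H-1": ManifestEntry(6, 3, 4, pooled=True, pooled_size=12),
}


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


@dataclass
class ValidationReport:
    benchmark: str
    violations: list[Violation]

    @property
    def passed(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# serialization


def _dataset_from_dict(data: dict, path=None) -> BenchmarkDataset:
    try:
        targets = [TargetSet(t["label"], list(t["terms"])) for t in data["targets"]]
        groups = [AttributeGroup(g["label"], list(g["terms"])) for g in data["attribute_groups"]]
        return BenchmarkDataset(
            name=data["name"],
            description=data.get("description", ""),
            targets=targets,
            attribute_groups=groups,
            references=list(data.get("references", [])),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed benchmark record: missing/invalid field {exc}", path=path) from exc


def _dataset_to_dict(ds: BenchmarkDataset) -> dict:
    return {
        "name": ds.name,
        "description": ds.description,
        "targets": [{"label": s.label, "terms": list(s.terms)} for s in ds.targets],
        "attribute_groups": [{"label": g.label, "terms": list(g.terms)} for g in ds.attribute_groups],
        "references": list(ds.references),
    }


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() in {".csv", ".tsv"} else "json"


def read_benchmark(
    path: str | Path,
    format: Literal["json", "csv"] | None = None,
    *,
    validate: bool = True,
) -> BenchmarkDataset:
    """Read a benchmark dataset file and (by default) enforce its invariants."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc.msg}", path=path, line=exc.lineno) from exc
        ds = _dataset_from_dict(data, path)
    elif fmt == "csv":
        ds = _read_csv(path)
    else:
        raise ValueError(f"unknown benchmark format {fmt!r}")
    if validate:
        ds.check()
    return ds


def _read_csv(path: Path) -> BenchmarkDataset:
    name, description = "", ""
    targets: dict[str, TargetSet] = {}
    groups: dict[str, AttributeGroup] = {}
    references: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if row != ["set_kind", "set_label", "term"]:
                    raise ParseError(
                        "expected header 'set_kind,set_label,term'", path=path, line=lineno
                    )
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ParseError(f"expected 3 columns, got {len(row)}", path=path, line=lineno)
            kind, label, term = row
            if kind == "meta":
                if label == "name":
                    name = term
                elif label == "description":
                    description = term
                else:
                    raise ParseError(f"unknown meta row {label!r}", path=path, line=lineno)
            elif kind == "target":
                targets.setdefault(label, TargetSet(label, [])).terms.append(_check_term(term))
            elif kind == "attribute":
                groups.setdefault(label, AttributeGroup(label, [])).terms.append(_check_term(term))
            elif kind == "reference":
                references.append(term)
            else:
                raise ParseError(f"unknown set_kind {kind!r}", path=path, line=lineno)
    if not name:
        raise ParseError("missing 'meta,name' row", path=path)
    return BenchmarkDataset(name, description, list(targets.values()), list(groups.values()), references)


def write_benchmark(
    ds: BenchmarkDataset, path: str | Path, format: Literal["json", "csv"] | None = None
) -> None:
    """Serialize a benchmark so that :func:`read_benchmark` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(
            json.dumps(_dataset_to_dict(ds), indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["set_kind", "set_label", "term"])
            writer.writerow(["meta", "name", ds.name])
            writer.writerow(["meta", "description", ds.description])
            for s in ds.targets:
                for t in s.terms:
                    writer.writerow(["target", s.label, t])
            for g in ds.attribute_groups:
                for t in g.terms:
                    writer.writerow(["attribute", g.label, t])
            for r in ds.references:
                writer.writerow(["reference", "", r])
    else:
        raise ValueError(f"unknown benchmark format {fmt!r}")


# ---------------------------------------------------------------------------
# validation against the manifest


def validate_benchmark(
    ds: BenchmarkDataset, manifest: dict[str, ManifestEntry] | None = None
) -> ValidationReport:
    """Check a dataset against its expected shape and structural invariants."""
    manifest = MANIFEST if manifest is None else manifest
    if ds.name not in manifest:
        raise KeyError(f"benchmark {ds.name!r} not in manifest (known: {sorted(manifest)})")
    entry = manifest[ds.name]
    violations = list(ds.violations())
    for s in ds.targets:
        if len(s) != entry.n_target_terms:
            violations.append(
                Violation("target-count", f"target {s.label!r}: {len(s)} != {entry.n_target_terms}")
            )
    if len(ds.attribute_groups) != entry.n_attribute_groups:
        violations.append(
            Violation(
                "group-count",
                f"attribute groups: {len(ds.attribute_groups)} != {entry.n_attribute_groups}",
            )
        )
    for g in ds.attribute_groups:
        if len(g) != entry.n_terms_per_group:
            violations.append(
                Violation("attribute-count", f"group {g.label!r}: {len(g)} != {entry.n_terms_per_group}")
            )
    if entry.pooled:
        pooled = sum(len(g) for g in ds.attribute_groups)
        if pooled != entry.pooled_size:
            violations.append(
                Violation("pooled-count", f"pooled attribute list: {pooled} != {entry.pooled_size}")
            )
    return ValidationReport(ds.name, violations)


# ---------------------------------------------------------------------------
# vocabulary filtering


def term_tokens(term: Term, *, split_hyphens: bool = False) -> list[str]:
    """Whitespace tokens of a term; hyphens kept unless ``split_hyphens``."""
    tokens = term.split()
    if split_hyphens:
        tokens = [p for tok in tokens for p in tok.replace("-", " ").split()]
    return tokens


def _representable(term: Term, vocab: set[str], split_hyphens: bool, lower: bool) -> bool:
    for tok in term_tokens(term, split_hyphens=split_hyphens):
        if tok in vocab:
            continue
        if lower and tok.lower() in vocab:
            continue
        return False
    return True


def filter_by_vocabulary(
    ds: BenchmarkDataset,
    vocab: Iterable[str],
    *,
    split_hyphens: bool = False,
    fallback_lower: bool = True,
) -> tuple[BenchmarkDataset, list[tuple[str, Term]]]:
    """Drop terms not representable in ``vocab``.

    A multi-word term is representable iff every whitespace token is in the
    vocabulary.  Dropped terms are reported as ``(set_label, term)`` pairs.
    Equal target-set sizes are *not* restored: the filtered dataset may be
    unbalanced and is returned unvalidated on that axis.
    """
    vocab = set(vocab)
    if not vocab:
        raise ValueError("vocabulary is empty")
    dropped: list[tuple[str, Term]] = []

    def _filter(s: _TermSet) -> list[Term]:
        kept = []
        for t in s.terms:
            if _representable(t, vocab, split_hyphens, fallback_lower):
                kept.append(t)
            else:
                dropped.append((s.label, t))
        if not kept:
            raise BenchmarkValidationError(
                ["empty-set-after-filter"], [f"every term of set {s.label!r} is out of vocabulary"]
            )
        return kept

    new = replace(
        ds,
        targets=[TargetSet(s.label, _filter(s)) for s in ds.targets],
        attribute_groups=[AttributeGroup(g.label, _filter(g)) for g in ds.attribute_groups],
    )
    new.check(require_equal_targets=False)
    return new, dropped


# ---------------------------------------------------------------------------
# bundled fixtures


def load_fixture(name: str, overrides_dir: str | Path | None = None) -> BenchmarkDataset:
    """Load a bundled benchmark fixture by name (``G-1`` .. ``H-1``).

    The bundled files carry the published example terms plus clearly marked
    placeholder slots so every set has its documented size.  When
    ``overrides_dir`` is given and contains ``<name>.json`` or ``<name>.csv``
    (e.g. full term lists transcribed from the published supplement), that
    file is loaded instead.
    """
    if overrides_dir is not None:
        for ext in ("json", "csv"):
            cand = Path(overrides_dir) / f"{name}.{ext}"
            if cand.exists():
                return read_benchmark(cand)
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown benchmark fixture {name!r} (known: {FIXTURE_NAMES})")
    ref = resources.files("medbias.data").joinpath(f"fixtures/{name}.json")
    with resources.as_file(ref) as path:
        return read_benchmark(path)


def load_all_fixtures(overrides_dir: str | Path | None = None) -> dict[str, BenchmarkDataset]:
    return {name: load_fixture(name, overrides_dir) for name in FIXTURE_NAMES}
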