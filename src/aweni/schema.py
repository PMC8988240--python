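"""Index schemas: the indicator -> theme -> domain-dimension hierarchy.

A composite empowerment index is organised as a two-level hierarchy: each
binary indicator belongs to a *theme* (a narrow aspect such as "Eating
norms"), and each theme belongs to one of seven *domain-dimensions* (DDs)
obtained by crossing the domains {food, health, institutions} with the
dimensions {knowledge, resources, agency} (institutions is undivided):

    FA  food-agency        FK  food-knowledge     FR  food-resources
    HA  health-agency      HK  health-knowledge   HR  health-resources
    I   institutions

Two schemas ship with the package as named fixtures: ``weni33`` (the full
33-indicator index) and ``aweni20`` (the abridged 20-indicator subset).
"""

from __future__ import annotations

import csv
from collections import Counter, OrderedDict
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "DD_CODES",
    "FIXTURES",
    "IndicatorDef",
    "IndexSchema",
    "CoverageReport",
    "SchemaError",
    "load_schema",
    "write_schema",
    "get_fixture",
    "theme_coverage",
]

#: The closed set of domain-dimension codes.
DD_CODES = ("FA", "FK", "FR", "HA", "HK", "HR", "I")

#: Names of the schema fixtures packaged with the library.
FIXTURES = ("weni33", "aweni20")


class SchemaError(ValueError):
    """Raised when a schema file or schema object violates its invariants."""


@dataclass(frozen=True)
class IndicatorDef:
    """One binary indicator: its name, DD code, theme label and description."""

    name: str
    dd: str
    theme: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise SchemaError("indicator name must be non-empty")
        if self.dd not in DD_CODES:
            raise SchemaError(
                f"unknown DD code {self.dd!r} for indicator {self.name!r}; "
                f"expected one of {DD_CODES}"
            )
        if not self.theme or not str(self.theme).strip():
            raise SchemaError(f"indicator {self.name!r} has an empty theme")


@dataclass(frozen=True)
class IndexSchema:
    """An ordered collection of indicators plus the empowerment threshold.

    The threshold is the composite-score cutoff at or above which a
    respondent is classified as empowered (default 0.5, inclusive).
    """

    indicators: tuple[IndicatorDef, ...]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.indicators:
            raise SchemaError("schema has no indicators")
        if not (0.0 <= self.threshold <= 1.0):
            raise SchemaError(f"threshold {self.threshold} outside [0, 1]")
        dupes = [n for n, c in Counter(self.names).items() if c > 1]
        if dupes:
            raise SchemaError(f"duplicate indicator name(s): {sorted(dupes)}")

    # -- interrogation ----------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ind.name for ind in self.indicators)

    @property
    def dds(self) -> tuple[str, ...]:
        """DD codes present, in first-appearance order."""
        seen: "OrderedDict[str, None]" = OrderedDict()
        for ind in self.indicators:
            seen.setdefault(ind.dd, None)
        return tuple(seen)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def indicators_by_dd(self) -> "OrderedDict[str, tuple[str, ...]]":
        out: "OrderedDict[str, list[str]]" = OrderedDict()
        for ind in self.indicators:
            out.setdefault(ind.dd, []).append(ind.name)
        return OrderedDict((dd, tuple(v)) for dd, v in out.items())

    def themes_by_dd(self) -> "OrderedDict[str, tuple[str, ...]]":
        """Distinct themes per DD, in first-appearance order."""
        out: "OrderedDict[str, OrderedDict[str, None]]" = OrderedDict()
        for ind in self.indicators:
            out.setdefault(ind.dd, OrderedDict()).setdefault(ind.theme, None)
        return OrderedDict((dd, tuple(v)) for dd, v in out.items())

    def dd_sizes(self) -> dict[str, int]:
        return {dd: len(names) for dd, names in self.indicators_by_dd().items()}

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.indicators)

    def subset(self, names: Sequence[str], threshold: float | None = None) -> "IndexSchema":
        """Restrict the schema to ``names``, preserving the original order."""
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise SchemaError(f"unknown indicator name(s): {sorted(unknown)}")
        kept = tuple(ind for ind in self.indicators if ind.name in wanted)
        return replace(
            self,
            indicators=kept,
            threshold=self.threshold if threshold is None else threshold,
        )


@dataclass(frozen=True)
class CoverageReport:
    """Per-DD theme coverage of an indicator subset against a full schema."""

    per_dd: Mapping[str, tuple[int, int, float]]  # dd -> (total, covered, pct)
    min_coverage: float
    cutoff: float
    passes: bool

    def to_frame(self):
        import pandas as pd

        rows = [
            {"dd": dd, "themes_total": t, "themes_covered": c, "coverage_pct": pct}
            for dd, (t, c, pct) in self.per_dd.items()
        ]
        return pd.DataFrame(rows).set_index("dd")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("name", "dd", "theme", "description")


def _rows_from_delimited(path: Path) -> list[dict]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing header with a 'name' column")
        return list(reader)


def _rows_from_yaml(path: Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, Mapping) and "indicators" in doc:
        doc = doc["indicators"]
    if not isinstance(doc, list):
        raise SchemaError(f"{path}: expected a list of indicator mappings")
    return [dict(row) for row in doc]


def load_schema(path, threshold: float = 0.5) -> IndexSchema:
    """Load a schema from a delimited table (csv/tsv) or a YAML document.

    Rows need columns ``name``, ``dd``, ``theme`` and optionally
    ``description``.  A blank ``theme`` cell inherits the nearest non-blank
    label above it within the same DD block (the merged-cell convention of
    printed indicator tables); a blank theme at the head of a DD block is an
    error.  Indicator order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"schema file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = _rows_from_yaml(path)
    else:
        rows = _rows_from_delimited(path)

    indicators: list[IndicatorDef] = []
    last_theme: dict[str, str] = {}
    for i, row in enumerate(rows):
        name = str(row.get("name") or "").strip()
        dd = str(row.get("dd") or "").strip()
        theme = str(row.get("theme") or "").strip()
        desc = str(row.get("description") or "").strip()
        if not theme:
            if dd not in last_theme:
                raise SchemaError(
                    f"{path}: row {i + 1} ({name!r}) has a blank theme with no "
                    f"preceding theme label in DD block {dd!r}"
                )
            theme = last_theme[dd]
        indicators.append(IndicatorDef(name=name, dd=dd, theme=theme, description=desc))
        last_theme[dd] = theme
    return IndexSchema(indicators=tuple(indicators), threshold=threshold)


def write_schema(schema: IndexSchema, path) -> None:
    """Write a schema as a UTF-8 CSV with the documented columns."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for ind in schema.indicators:
            writer.writerow([ind.name, ind.dd, ind.theme, ind.description])


def get_fixture(name: str, threshold: float = 0.5) -> IndexSchema:
    """Return a packaged schema fixture by name (``weni33`` or ``aweni20``)."""
    if name not in FIXTURES:
        raise SchemaError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("aweni.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return load_schema(p, threshold=threshold)


def resolve_schema(spec, threshold: float = 0.5) -> IndexSchema:
    """Accept an IndexSchema, a fixture name, or a file path."""
    if isinstance(spec, IndexSchema):
        return spec
    if isinstance(spec, (str, Path)) and str(spec) in FIXTURES:
        return get_fixture(str(spec), threshold=threshold)
    return load_schema(spec, threshold=threshold)


# ---------------------------------------------------------------------------
# Theme coverage
# ---------------------------------------------------------------------------

def theme_coverage(
    full: IndexSchema, subset: Iterable[str], cutoff: float = 50.0
) -> CoverageReport:
    """Theme coverage of ``subset`` per DD of ``full``, in percent.

    A theme counts as covered when the subset retains at least one of its
    indicators; a DD's coverage is 100 x covered / total themes.  ``passes``
    is True when the minimum coverage over DDs reaches ``cutoff`` (>=,
    inclusive) — the guard that keeps an abbreviated index from becoming
    lopsided.
    """
    subset = list(subset)
    unknown = set(subset) - set(full.names)
    if unknown:
        raise SchemaError(f"subset contains unknown indicator(s): {sorted(unknown)}")
    kept = set(subset)

    covered_themes: dict[str, set[str]] = {dd: set() for dd in full.dds}
    for ind in full.indicators:
        if ind.name in kept:
            covered_themes[ind.dd].add(ind.theme)

    per_dd: "OrderedDict[str, tuple[int, int, float]]" = OrderedDict()
    for dd, themes in full.themes_by_dd().items():
        total = len(themes)
        cov = len(covered_themes[dd])
        per_dd[dd] = (total, cov, 100.0 * cov / total)
    min_cov = min(pct for _, _, pct in per_dd.values())
    return CoverageReport(
        per_dd=per_dd, min_coverage=min_cov, cutoff=cutoff, passes=min_cov >= cutoff
    )
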