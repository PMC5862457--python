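"""Response matrices and scale definitions.

Ordinal questionnaire responses are held as a persons x items matrix of
float scores in ``0..K`` with ``NaN`` marking a missing response.  External
Likert codes run ``1..K+1``; they are shifted down on load so that the
lowest category is 0, the indexing the Rating Scale Model uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateDataError, FormatError

__all__ = [
    "ResponseMatrix",
    "ScaleDefinition",
    "load_responses",
    "write_responses",
    "load_scale_definition",
    "apply_reverse_keying",
    "filter_missing_persons",
    "subset_dimension",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items ordinal responses with explicit missingness.

    Parameters
    ----------
    person_ids, item_ids
        Unique opaque identifiers, in matrix order.
    responses
        Float array of shape ``(n_persons, n_items)`` with values in
        ``{0..n_categories-1}`` or ``NaN`` for missing.
    n_categories
        Number of response categories ``K + 1`` (five for a 1..5 Likert).
    """

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    responses: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "person_ids", tuple(str(p) for p in self.person_ids))
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        arr = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", arr)
        if len(set(self.person_ids)) != len(self.person_ids):
            raise FormatError("duplicate person ids")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise FormatError("duplicate item ids")
        if arr.shape != (len(self.person_ids), len(self.item_ids)):
            raise FormatError(
                f"response matrix shape {arr.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.item_ids)} items"
            )
        if self.n_categories < 2:
            raise ConfigurationError("need at least 2 response categories")
        observed = arr[~np.isnan(arr)]
        if observed.size:
            if not np.allclose(observed, np.round(observed)):
                raise FormatError("non-integer response scores")
            if observed.min() < 0 or observed.max() > self.n_categories - 1:
                raise FormatError(
                    "response scores outside the category range "
                    f"[0, {self.n_categories - 1}]"
                )

    # -- basic views ---------------------------------------------------

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def max_score(self) -> int:
        """Top category index K."""
        return self.n_categories - 1

    def missing_fraction(self) -> np.ndarray:
        """Per-person fraction of missing responses."""
        return np.isnan(self.responses).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.responses, index=list(self.person_ids), columns=list(self.item_ids)
        )

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        unknown = [i for i in item_ids if i not in self.item_ids]
        if unknown:
            raise ConfigurationError(f"unknown item ids: {unknown}")
        cols = [self.item_ids.index(i) for i in item_ids]
        return replace(
            self, item_ids=tuple(item_ids), responses=self.responses[:, cols]
        )

    def subset_persons(self, person_ids: Sequence[str]) -> "ResponseMatrix":
        unknown = [p for p in person_ids if p not in self.person_ids]
        if unknown:
            raise ConfigurationError(f"unknown person ids: {unknown}")
        rows = [self.person_ids.index(p) for p in person_ids]
        return replace(
            self, person_ids=tuple(person_ids), responses=self.responses[rows, :]
        )

    def equals(self, other: "ResponseMatrix") -> bool:
        return (
            self.person_ids == other.person_ids
            and self.item_ids == other.item_ids
            and self.n_categories == other.n_categories
            and np.array_equal(self.responses, other.responses, equal_nan=True)
        )


@dataclass(frozen=True)
class ScaleDefinition:
    """Mapping of items to dimensions, short-form membership and keying."""

    dimensions: Mapping[str, tuple[str, ...]]
    short_form: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    reverse_keyed: frozenset[str] = frozenset()
    n_categories: int = 5

    def __post_init__(self) -> None:
        dims = {str(d): tuple(str(i) for i in items) for d, items in self.dimensions.items()}
        short = {str(d): tuple(str(i) for i in items) for d, items in self.short_form.items()}
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "short_form", short)
        object.__setattr__(self, "reverse_keyed", frozenset(str(i) for i in self.reverse_keyed))
        seen: set[str] = set()
        for dim, items in dims.items():
            if len(items) < 4:
                raise ConfigurationError(f"dimension {dim!r} has fewer than 4 items")
            if seen & set(items):
                raise ConfigurationError(f"dimension {dim!r} shares items with another dimension")
            seen |= set(items)
        for dim, items in short.items():
            if dim not in dims:
                raise ConfigurationError(f"short form names unknown dimension {dim!r}")
            if len(items) < 2:
                raise ConfigurationError(f"short form of {dim!r} has fewer than 2 items")
            stray = set(items) - set(dims[dim])
            if stray:
                raise ConfigurationError(
                    f"short-form items {sorted(stray)} not in dimension {dim!r}"
                )

    @property
    def all_items(self) -> tuple[str, ...]:
        out: list[str] = []
        for items in self.dimensions.values():
            out.extend(items)
        return tuple(out)

    def items_for(self, dimension: str, version: str = "full") -> tuple[str, ...]:
        """Ordered item ids of a dimension, full or short version."""
        if dimension not in self.dimensions:
            raise ConfigurationError(f"unknown dimension {dimension!r}")
        if version == "full":
            return self.dimensions[dimension]
        if version == "short":
            if dimension not in self.short_form:
                raise ConfigurationError(f"no short form defined for {dimension!r}")
            return self.short_form[dimension]
        raise ConfigurationError(f"unknown version {version!r}; use 'full' or 'short'")

    def to_dict(self) -> dict:
        return {
            "dimensions": {d: list(v) for d, v in self.dimensions.items()},
            "short_form": {d: list(v) for d, v in self.short_form.items()},
            "reverse_keyed": sorted(self.reverse_keyed),
            "n_categories": self.n_categories,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))


def load_scale_definition(path: str | Path) -> ScaleDefinition:
    """Read a ScaleDefinition from a JSON or YAML document."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    if not isinstance(doc, dict) or "dimensions" not in doc:
        raise ConfigurationError(f"{path}: scale definition must define 'dimensions'")
    return ScaleDefinition(
        dimensions=doc["dimensions"],
        short_form=doc.get("short_form", {}),
        reverse_keyed=frozenset(doc.get("reverse_keyed", [])),
        n_categories=int(doc.get("n_categories", 5)),
    )


def load_responses(
    path: str | Path,
    missing_codes: Iterable[str] = ("", "NA"),
    n_categories: int = 5,
    sep: str | None = None,
) -> ResponseMatrix:
    """Load a delimited response file into a :class:`ResponseMatrix`.

    The file has a header row of item ids, a first column of person ids,
    and cells holding external Likert codes ``1..K+1`` or a missing code.
    Scores are shifted to the internal ``0..K`` range.  Row and column
    order is preserved.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    missing = {str(m) for m in missing_codes}
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    person_ids = [str(p) for p in df.index]
    item_ids = [str(c) for c in df.columns]
    if len(set(person_ids)) != len(person_ids):
        raise FormatError(f"{path}: duplicate person ids")
    if len(set(item_ids)) != len(item_ids):
        raise FormatError(f"{path}: duplicate item ids")
    scores = np.full(df.shape, np.nan)
    for j, item in enumerate(item_ids):
        col = df.iloc[:, j].astype(str).str.strip()
        for i, raw in enumerate(col):
            if raw in missing:
                continue
            try:
                value = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer cell {raw!r} at person {person_ids[i]!r}, "
                    f"item {item!r}"
                ) from None
            if not 1 <= value <= n_categories:
                raise FormatError(
                    f"{path}: score {value} out of range 1..{n_categories} at "
                    f"person {person_ids[i]!r}, item {item!r}"
                )
            scores[i, j] = value - 1
    return ResponseMatrix(
        person_ids=tuple(person_ids),
        item_ids=tuple(item_ids),
        responses=scores,
        n_categories=n_categories,
    )


def write_responses(rm: ResponseMatrix, path: str | Path, missing_code: str = "") -> None:
    """Write a ResponseMatrix back to delimited text with external 1..K+1 codes."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    external = rm.responses + 1
    df = pd.DataFrame(external, index=list(rm.person_ids), columns=list(rm.item_ids))
    df = df.map(lambda v: missing_code if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep=sep, index_label="person")


def apply_reverse_keying(rm: ResponseMatrix, scale: ScaleDefinition) -> ResponseMatrix:
    """Recode reverse-keyed items ``x -> K - x``; missing stays missing."""
    unknown = [i for i in scale.reverse_keyed if i not in rm.item_ids]
    if unknown:
        raise ConfigurationError(f"reverse-keyed items not in matrix: {sorted(unknown)}")
    if not scale.reverse_keyed:
        return rm
    scores = rm.responses.copy()
    cols = [j for j, item in enumerate(rm.item_ids) if item in scale.reverse_keyed]
    scores[:, cols] = rm.max_score - scores[:, cols]
    return replace(rm, responses=scores)


def filter_missing_persons(
    rm: ResponseMatrix, max_missing_fraction: float = 0.20
) -> tuple[ResponseMatrix, list[str]]:
    """Drop persons whose missing fraction strictly exceeds the threshold.

    The threshold is evaluated on the matrix as given — the full
    administered scale, before any dimension subsetting — and the boundary
    is strict: a person with exactly the threshold fraction is retained.

    Returns the retained matrix and the excluded person ids.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ConfigurationError("max_missing_fraction must be in [0, 1)")
    frac = rm.missing_fraction()
    keep = frac <= max_missing_fraction
    excluded = [p for p, k in zip(rm.person_ids, keep) if not k]
    if not keep.any():
        raise DegenerateDataError("all persons exceed the missing-data threshold")
    retained = replace(
        rm,
        person_ids=tuple(p for p, k in zip(rm.person_ids, keep) if k),
        responses=rm.responses[keep, :],
    )
    return retained, excluded


def subset_dimension(
    rm: ResponseMatrix,
    scale: ScaleDefinition,
    dimension: str,
    version: str = "full",
) -> ResponseMatrix:
    """Restrict columns to one dimension's (full or short) items.

    Column order follows the ScaleDefinition; persons are unchanged.
    """
    items = scale.items_for(dimension, version)
    missing_items = [i for i in items if i not in rm.item_ids]
    if missing_items:
        raise ConfigurationError(
            f"items {missing_items} of dimension {dimension!r} not present in responses"
        )
    return rm.subset_items(items)
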