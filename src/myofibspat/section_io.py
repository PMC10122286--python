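"""Reading, validation and encoding of per-fiber section data.

A *section* is one histological muscle cross-section reduced to a table with
one row per fiber: the planar centroid coordinates ``(x, y)`` and a
categorical fiber-type label (e.g. ``I`` / ``IIA``).  Coordinates are
unitless; every statistic in this package is invariant to translation and
uniform scaling of the coordinates.

Fiber-type labels are compared case-insensitively after stripping
surrounding whitespace; the mapping of labels onto the slow/fast dichotomy
is always explicit (no hard-coded histochemical conventions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SectionError",
    "SectionFormatError",
    "SectionValidationError",
    "LabelMappingError",
    "DegenerateSectionError",
    "FiberSection",
    "BinaryLabels",
    "read_section_csv",
    "write_section_csv",
    "encode_binary",
    "write_results",
    "read_results",
]

logger = logging.getLogger("myofibspat")

SLOW = -1  #: spin value of a slow-type fiber
FAST = +1  #: spin value of a fast-type fiber


class SectionError(Exception):
    """Base class for section input errors."""


class SectionFormatError(SectionError):
    """The input file does not have the expected columns/encoding."""


class SectionValidationError(SectionError):
    """The parsed table violates a section invariant."""


class LabelMappingError(SectionError):
    """A fiber-type label could not be assigned to slow or fast."""


class DegenerateSectionError(SectionError):
    """A section on which a statistic is undefined (e.g. a single type)."""


def _norm_label(label: object) -> str:
    return str(label).strip().casefold()


@dataclass(frozen=True)
class FiberSection:
    """One muscle cross-section: fiber centroids plus type labels.

    ``fiber_id`` is implicit: the dense 0-based array index, preserving the
    input row order.
    """

    x: np.ndarray
    y: np.ndarray
    type_label: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        labels = np.asarray([str(v).strip() for v in np.asarray(self.type_label)], dtype=object)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "type_label", labels)
        if x.ndim != 1 or y.ndim != 1 or labels.ndim != 1:
            raise SectionValidationError("x, y and type_label must be one-dimensional")
        if not (len(x) == len(y) == len(labels)):
            raise SectionValidationError("x, y and type_label must have equal length")
        if len(x) < 3:
            raise SectionValidationError(f"a section needs at least 3 fibers, got {len(x)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
            raise SectionValidationError(f"non-finite coordinates at rows {bad.tolist()}")
        # duplicate centroids break the geometry (zero-length edges, Voronoi ties)
        pts = x + 1j * y
        order = np.argsort(pts)
        dup = np.flatnonzero(pts[order][1:] == pts[order][:-1])
        if dup.size:
            pairs = sorted(
                sorted((int(order[i]), int(order[i + 1]))) for i in dup
            )
            raise SectionValidationError(f"duplicate (x, y) coordinates at row pairs {pairs}")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of centroids."""
        return np.column_stack([self.x, self.y])

    @property
    def type_counts(self) -> dict[str, int]:
        return dict(Counter(self.type_label))

    @property
    def types(self) -> tuple[str, ...]:
        """Distinct labels, most frequent first (ties broken alphabetically)."""
        counts = Counter(self.type_label)
        return tuple(sorted(counts, key=lambda t: (-counts[t], t)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FiberSection):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and bool((self.type_label == other.type_label).all())
        )


@dataclass(frozen=True)
class BinaryLabels:
    """Spin encoding of a two-class section: slow = -1, fast = +1."""

    z: np.ndarray
    n_slow: int
    n_fast: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int8)
        object.__setattr__(self, "z", z)
        if not np.isin(z, (-1, 1)).all():
            raise SectionValidationError("spins must be -1 or +1")
        if int((z == SLOW).sum()) != self.n_slow or int((z == FAST).sum()) != self.n_fast:
            raise SectionValidationError("spin counts inconsistent with n_slow/n_fast")

    @property
    def n(self) -> int:
        return len(self.z)

    @classmethod
    def from_spins(cls, z: np.ndarray) -> "BinaryLabels":
        z = np.asarray(z, dtype=np.int8)
        return cls(z=z, n_slow=int((z == SLOW).sum()), n_fast=int((z == FAST).sum()))

    def flipped(self) -> "BinaryLabels":
        """Swap the slow/fast roles (negate every spin)."""
        return BinaryLabels(z=-self.z, n_slow=self.n_fast, n_fast=self.n_slow)


def read_section_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> FiberSection:
    """Read a per-fiber section CSV with columns for x, y and fiber type.

    Parameters
    ----------
    path:
        CSV file with a header row; comma-separated, decimal point, UTF-8.
    column_map:
        Optional mapping ``{"x": ..., "y": ..., "type": ...}`` naming the
        columns to use when the file does not follow the default header
        names ``x``, ``y``, ``type`` (matched case-insensitively).
    """
    path = Path(path)
    if not path.exists():
        raise SectionFormatError(f"no such file: {path}")
    try:
        table = pd.read_csv(path, dtype=str, skipinitialspace=True, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SectionFormatError(f"could not parse {path}: {exc}") from exc

    wanted = {"x": "x", "y": "y", "type": "type"}
    if column_map:
        wanted.update({k: v for k, v in column_map.items() if k in wanted})
    lower = {str(c).strip().casefold(): c for c in table.columns}
    cols: dict[str, str] = {}
    for role, name in wanted.items():
        key = name.strip().casefold()
        if key not in lower:
            raise SectionFormatError(
                f"{path}: missing required column {name!r} (for {role}); "
                f"available columns: {list(table.columns)}"
            )
        cols[role] = lower[key]

    coords = {}
    for role in ("x", "y"):
        # float() is correctly rounded, so coordinates survive a write/read
        # round trip bit-for-bit (pandas' fast to_numeric parser does not)
        values = np.empty(len(table), dtype=np.float64)
        bad = []
        for row, raw in enumerate(table[cols[role]]):
            try:
                values[row] = float(raw)
            except (TypeError, ValueError):
                bad.append(row)
        if bad:
            raise SectionFormatError(
                f"{path}: non-numeric {role} coordinate at data row(s) {bad}"
            )
        coords[role] = values

    labels = table[cols["type"]].astype(str).str.strip()
    section = FiberSection(x=coords["x"], y=coords["y"], type_label=labels.to_numpy(object), source=str(path))
    if len({_norm_label(t) for t in section.type_label}) < 2:
        raise SectionValidationError(
            f"{path}: only one fiber type present; spatial statistics are undefined"
        )
    logger.info(
        "read section %s: n=%d, type counts=%s", path.name, section.n, section.type_counts
    )
    return section


def write_section_csv(section: FiberSection, path: str | Path) -> Path:
    """Write a section back to the standard (x, y, type) CSV layout.

    Coordinates are written with shortest round-trip ``repr`` so that
    reading the file back reproduces them bit-for-bit.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y,type\n")
        for xi, yi, ti in zip(section.x, section.y, section.type_label):
            fh.write(f"{float(xi)!r},{float(yi)!r},{ti}\n")
    return path


def encode_binary(
    section: FiberSection,
    fast_labels: Iterable[str],
    slow_labels: Iterable[str] | None = None,
) -> BinaryLabels:
    """Encode fiber types as spins: fast -> +1, slow -> -1.

    Labels in ``fast_labels`` map to +1; everything else maps to -1 unless
    ``slow_labels`` is given, in which case any label in neither set raises
    :class:`LabelMappingError`.  Label matching ignores case and surrounding
    whitespace.
    """
    fast = {_norm_label(t) for t in fast_labels}
    norm = np.array([_norm_label(t) for t in section.type_label], dtype=object)
    if slow_labels is not None:
        slow = {_norm_label(t) for t in slow_labels}
        unknown = sorted(set(norm) - fast - slow)
        if unknown:
            raise LabelMappingError(f"labels in neither fast nor slow set: {unknown}")
    is_fast = np.isin(norm, sorted(fast))
    z = np.where(is_fast, FAST, SLOW).astype(np.int8)
    labels = BinaryLabels.from_spins(z)
    if labels.n_slow == 0 or labels.n_fast == 0:
        raise DegenerateSectionError(
            "binary encoding produced a single-type section "
            f"(n_slow={labels.n_slow}, n_fast={labels.n_fast}); "
            "tests and models are undefined"
        )
    return labels


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------
# Every result object in this package is a flat dataclass built from plain
# Python scalars/tuples, so a JSON dump round-trips field-for-field.

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls: type) -> type:
    """Class decorator adding a result dataclass to the (de)serialization registry."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    return obj


def result_payload(result) -> dict:
    """JSON-ready dict of a result dataclass (kind, package version, fields)."""
    from . import __version__

    if not dataclasses.is_dataclass(result):
        raise TypeError(f"expected a result dataclass, got {type(result)!r}")
    return {
        "_kind": type(result).__name__,
        "_package": "myofibspat",
        "_version": __version__,
        "fields": {f.name: _jsonable(getattr(result, f.name)) for f in dataclasses.fields(result)},
    }


def write_results(result, path: str | Path) -> Path:
    """Serialize a result dataclass to JSON (or a flat one-row CSV).

    JSON output embeds the result kind and the package version and
    round-trips losslessly through :func:`read_results`.  A ``.csv`` suffix
    writes a flat single-row table of the scalar fields instead (lossy for
    nested fields; intended for spreadsheets, not round-trips).
    """
    path = Path(path)
    payload = result_payload(result)
    try:
        if path.suffix.lower() == ".csv":
            flat = {
                k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
                for k, v in payload["fields"].items()
            }
            pd.DataFrame([flat]).to_csv(path, index=False)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2)
                fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def read_results(path: str | Path):
    """Reconstruct a result object written by :func:`write_results` (JSON only)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.get("_kind")
    cls = _RESULT_REGISTRY.get(kind)
    if cls is None:
        raise ValueError(f"{path}: unknown result kind {kind!r}")
    fields = {k: _tuplify(v) for k, v in payload["fields"].items()}
    return cls(**fields)
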