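"""Domain types for harmonized food-composition panels and bibliographic corpora.

Food composition databases (FCDBs) report, for each food, the quantity of
nutrients and other biochemical components per 100 g of edible portion.  Two
chronic ambiguities make naive comparisons across databases unreliable:

* a value of ``0`` may mean *measured and absent*, *below detection limit*,
  or simply *never analyzed* — most tables do not distinguish these;
* values are frequently copied ("borrowed") between databases rather than
  measured, so agreement across sources can reflect a shared origin rather
  than a shared food supply.

The types here force those distinctions to be explicit: every component value
carries a three-way :class:`ValueStatus` and a :class:`SourceKind`, and the
panel container rejects duplicate (food, database, component) entries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import IntegrityError

__all__ = [
    "ValueStatus",
    "SourceKind",
    "ComponentValue",
    "FCDBPanel",
    "Document",
    "UnitSpec",
    "UNITS",
    "FATTY_ACID_CLASS_IDS",
    "fatty_acid_class",
]


class ValueStatus(str, enum.Enum):
    """What a database actually asserts about a component quantity."""

    QUANTIFIED = "quantified"          #: a measured/compiled amount, >= 0
    ZERO_REPORTED = "zero_reported"    #: an explicit zero (measured or assumed)
    NOT_REPORTED = "not_reported"      #: no value at all


class SourceKind(str, enum.Enum):
    """Where a value came from, as far as the database documents it."""

    DIRECT_ANALYSIS = "direct_analysis"
    LITERATURE = "literature"
    BORROWED = "borrowed"              #: copied verbatim from another FCDB
    COMPILED = "compiled"
    UNKNOWN = "unknown"


#: Canonical fatty-acid class aggregate identifiers. ``TFA`` (trans) is
#: included because several databases report it alongside the other three;
#: callers that exclude trans simply pass a smaller class set.
FATTY_ACID_CLASS_IDS = ("SFA", "MUFA", "PUFA", "TFA")

YEAR_MIN, YEAR_MAX = 1900, 2100


def fatty_acid_class(component_id: str) -> Optional[str]:
    """Classify a leaf fatty acid id in ``FA<C>:<D>[t]`` notation.

    Returns ``"SFA"`` for zero double bonds, ``"MUFA"`` for one, ``"PUFA"``
    for two or more, ``"TFA"`` for a trailing ``t`` (trans), and ``None``
    for anything that is not a leaf fatty acid (including the class
    aggregates themselves).
    """
    if component_id in FATTY_ACID_CLASS_IDS or not component_id.startswith("FA"):
        return None
    body = component_id[2:]
    trans = body.endswith("t")
    if trans:
        body = body[:-1]
    try:
        _carbons, dbonds = body.split(":")
        n_double = int(dbonds)
        int(_carbons)
    except ValueError:
        return None
    if trans:
        return "TFA"
    if n_double == 0:
        return "SFA"
    if n_double == 1:
        return "MUFA"
    return "PUFA"


@dataclass(frozen=True)
class UnitSpec:
    """A mass-per-100 g unit and its multiplicative conversion to g/100 g."""

    unit_name: str
    factor_to_g: float

    def __post_init__(self) -> None:
        if self.factor_to_g not in (1.0, 1e-3, 1e-6):
            raise IntegrityError(
                f"unsupported conversion factor {self.factor_to_g!r} for unit "
                f"{self.unit_name!r}; expected 1, 1e-3 or 1e-6"
            )


#: Supported units keyed by canonical name, with common spelling aliases.
UNITS: Mapping[str, UnitSpec] = {
    "g/100g": UnitSpec("g/100g", 1.0),
    "mg/100g": UnitSpec("mg/100g", 1e-3),
    "µg/100g": UnitSpec("µg/100g", 1e-6),
}

UNIT_ALIASES: Mapping[str, str] = {
    "g/100g": "g/100g",
    "g": "g/100g",
    "mg/100g": "mg/100g",
    "mg": "mg/100g",
    "µg/100g": "µg/100g",
    "ug/100g": "µg/100g",
    "mcg/100g": "µg/100g",
    "µg": "µg/100g",
    "ug": "µg/100g",
    "mcg": "µg/100g",
}


@dataclass(frozen=True)
class ComponentValue:
    """One (food, database, component) measurement, harmonized to g/100 g.

    Invariants enforced at construction:

    * ``status == QUANTIFIED``   => ``quantity`` present and >= 0
    * ``status == ZERO_REPORTED``=> ``quantity == 0``
    * ``status == NOT_REPORTED`` => ``quantity`` absent
    * ``year``, when present, lies in [1900, 2100]
    """

    food_id: str
    db_id: str
    component_id: str
    status: ValueStatus
    quantity: Optional[float] = None
    year: Optional[int] = None
    source_kind: SourceKind = SourceKind.UNKNOWN
    source_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.food_id or not self.db_id or not self.component_id:
            raise IntegrityError("food_id, db_id and component_id must be non-empty")
        status = ValueStatus(self.status)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "source_kind", SourceKind(self.source_kind))
        if status is ValueStatus.QUANTIFIED:
            if self.quantity is None or math.isnan(self.quantity):
                raise IntegrityError(
                    f"{self.key()}: quantified record requires a quantity"
                )
            if self.quantity < 0:
                raise IntegrityError(f"{self.key()}: negative quantity {self.quantity}")
            object.__setattr__(self, "quantity", float(self.quantity))
        elif status is ValueStatus.ZERO_REPORTED:
            if self.quantity not in (None, 0, 0.0):
                raise IntegrityError(
                    f"{self.key()}: zero_reported record with quantity {self.quantity}"
                )
            object.__setattr__(self, "quantity", 0.0)
        else:  # NOT_REPORTED
            if self.quantity is not None and not math.isnan(self.quantity):
                raise IntegrityError(
                    f"{self.key()}: not_reported record must carry no quantity"
                )
            object.__setattr__(self, "quantity", None)
        if self.year is not None:
            if not (YEAR_MIN <= self.year <= YEAR_MAX):
                raise IntegrityError(f"{self.key()}: year {self.year} outside [1900, 2100]")
            object.__setattr__(self, "year", int(self.year))

    def key(self) -> tuple[str, str, str]:
        return (self.food_id, self.db_id, self.component_id)

    @property
    def is_reported(self) -> bool:
        """True when the database asserts *something* (a value or an explicit 0)."""
        return self.status is not ValueStatus.NOT_REPORTED

    @property
    def is_nonzero(self) -> bool:
        """True when a strictly positive quantity was reported."""
        return self.status is ValueStatus.QUANTIFIED and (self.quantity or 0.0) > 0


class FCDBPanel:
    """A multi-database food x component panel with unique record keys.

    Parameters
    ----------
    records
        The component values. At most one record per
        ``(food_id, db_id, component_id)`` triple.
    food_ids, db_ids, component_ids
        Optional declared index sets. Defaults to the identifiers present in
        ``records``; passing supersets lets coverage matrices report explicit
        zero rows/columns for entities with no records at all.
    """

    def __init__(
        self,
        records: Iterable[ComponentValue],
        food_ids: Optional[Sequence[str]] = None,
        db_ids: Optional[Sequence[str]] = None,
        component_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.records: tuple[ComponentValue, ...] = tuple(records)
        index: dict[tuple[str, str, str], ComponentValue] = {}
        for rec in self.records:
            if rec.key() in index:
                raise IntegrityError(f"duplicate record for {rec.key()}")
            index[rec.key()] = rec
        self._index = index
        present_foods = {r.food_id for r in self.records}
        present_dbs = {r.db_id for r in self.records}
        present_comps = {r.component_id for r in self.records}
        for declared, present, name in (
            (food_ids, present_foods, "food_ids"),
            (db_ids, present_dbs, "db_ids"),
            (component_ids, present_comps, "component_ids"),
        ):
            if declared is not None and not present <= set(declared):
                raise IntegrityError(f"declared {name} do not cover the records")
        self.food_ids = tuple(sorted(food_ids) if food_ids is not None else sorted(present_foods))
        self.db_ids = tuple(sorted(db_ids) if db_ids is not None else sorted(present_dbs))
        self.component_ids = tuple(
            sorted(component_ids) if component_ids is not None else sorted(present_comps)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FCDBPanel):
            return NotImplemented
        return (
            sorted(self.records, key=ComponentValue.key)
            == sorted(other.records, key=ComponentValue.key)
            and self.food_ids == other.food_ids
            and self.db_ids == other.db_ids
            and self.component_ids == other.component_ids
        )

    def get(self, food_id: str, db_id: str, component_id: str) -> Optional[ComponentValue]:
        return self._index.get((food_id, db_id, component_id))

    def select(
        self,
        foods: Optional[Iterable[str]] = None,
        dbs: Optional[Iterable[str]] = None,
        components: Optional[Iterable[str]] = None,
    ) -> list[ComponentValue]:
        """Records matching every given filter (``None`` = no constraint)."""
        fs = set(foods) if foods is not None else None
        ds = set(dbs) if dbs is not None else None
        cs = set(components) if components is not None else None
        return [
            r
            for r in self.records
            if (fs is None or r.food_id in fs)
            and (ds is None or r.db_id in ds)
            and (cs is None or r.component_id in cs)
        ]

    def to_frame(self):
        """Long-form :class:`pandas.DataFrame` view of the records."""
        import pandas as pd

        return pd.DataFrame(
            {
                "food_id": [r.food_id for r in self.records],
                "db_id": [r.db_id for r in self.records],
                "component_id": [r.component_id for r in self.records],
                "quantity": [r.quantity for r in self.records],
                "status": [r.status.value for r in self.records],
                "year": [r.year for r in self.records],
                "source_kind": [r.source_kind.value for r in self.records],
                "source_ref": [r.source_ref for r in self.records],
            }
        )


@dataclass(frozen=True)
class Document:
    """A bibliographic record: title/abstract text plus its reference list.

    ``references`` point *from* this document *to* the documents it cites;
    targets need not exist in the same corpus (dangling references are kept
    at load time and filtered when a citation graph is built).
    Self-citations are disallowed.
    """

    doc_id: str
    title: str
    abstract: str = ""
    year: Optional[int] = None
    references: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise IntegrityError("doc_id must be non-empty")
        object.__setattr__(self, "references", tuple(self.references))
        if self.doc_id in self.references:
            raise IntegrityError(f"document {self.doc_id!r} cites itself")

    @property
    def text(self) -> str:
        """Title and abstract joined — the text the filtering/labeling stages see."""
        return f"{self.title} {self.abstract}".strip()
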