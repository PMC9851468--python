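"""Profiling the age of food-composition data.

Most databases attach at best a publication year to each value, and a value
extracted from a compilation may have been measured long before that year.
The dates profiled here are therefore *upper bounds* on the measurement date
whenever the source is literature, a compilation, or a borrowed value; every
report carries that caveat explicitly.

Three views are provided: decade histograms, the fraction of dated values
collected before a cutoff year, and per-record staleness flags against a
maximum acceptable age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import DomainError
from .model import ComponentValue, FCDBPanel, SourceKind

__all__ = [
    "Scope",
    "DecadeProfile",
    "FractionBefore",
    "decade_histogram",
    "fraction_before",
    "staleness_flags",
]

#: Source kinds for which the attached date is an upper bound on the
#: measurement date rather than the measurement date itself.
DATE_IS_UPPER_BOUND_KINDS = frozenset(
    {SourceKind.LITERATURE, SourceKind.COMPILED, SourceKind.BORROWED}
)

UPPER_BOUND_CAVEAT = (
    "dates on literature/compiled/borrowed values bound the measurement date "
    "from above; the value may have been measured earlier"
)


@dataclass(frozen=True)
class Scope:
    """Optional food/database/component filters; ``None`` means unrestricted."""

    foods: Optional[frozenset] = None
    dbs: Optional[frozenset] = None
    components: Optional[frozenset] = None

    @classmethod
    def of(cls, foods=None, dbs=None, components=None) -> "Scope":
        return cls(
            foods=frozenset(foods) if foods is not None else None,
            dbs=frozenset(dbs) if dbs is not None else None,
            components=frozenset(components) if components is not None else None,
        )

    def matches(self, rec: ComponentValue) -> bool:
        return (
            (self.foods is None or rec.food_id in self.foods)
            and (self.dbs is None or rec.db_id in self.dbs)
            and (self.components is None or rec.component_id in self.components)
        )


def _in_mode(rec: ComponentValue, mode: str) -> bool:
    if mode == "reported":
        return rec.is_reported
    if mode == "nonzero":
        return rec.is_nonzero
    raise ValueError(f"mode must be 'reported' or 'nonzero', got {mode!r}")


def _scoped(panel: FCDBPanel, scope: Scope, mode: str) -> list[ComponentValue]:
    return [r for r in panel if scope.matches(r) and _in_mode(r, mode)]


@dataclass
class DecadeProfile:
    """Counts of records by decade of their attached year.

    ``bins`` maps decade start years (multiples of 10; half-open [Y, Y+10))
    to record counts; ``undated`` counts records without a year. The two
    always add up to the number of in-scope records.
    """

    mode: str
    bins: dict[int, int] = field(default_factory=dict)
    undated: int = 0
    caveats: tuple[str, ...] = (UPPER_BOUND_CAVEAT,)

    @property
    def total(self) -> int:
        return sum(self.bins.values()) + self.undated


def decade_histogram(
    panel: FCDBPanel, scope: Scope = Scope(), mode: str = "reported"
) -> DecadeProfile:
    """Bin in-scope records by decade (floor(year/10)*10); undated kept apart."""
    bins: dict[int, int] = {}
    undated = 0
    for rec in _scoped(panel, scope, mode):
        if rec.year is None:
            undated += 1
        else:
            decade = (rec.year // 10) * 10
            bins[decade] = bins.get(decade, 0) + 1
    return DecadeProfile(mode=mode, bins=dict(sorted(bins.items())), undated=undated)


@dataclass(frozen=True)
class FractionBefore:
    """Share of *dated* in-scope records older than a cutoff year.

    Undated records are excluded from numerator and denominator; their count
    is carried alongside so the reader can judge how partial the statistic is.
    """

    cutoff: int
    fraction: float
    n_dated: int
    n_undated: int


def fraction_before(
    panel: FCDBPanel, scope: Scope = Scope(), year: int = 1990, mode: str = "reported"
) -> FractionBefore:
    """Fraction of dated records with ``record.year < year``.

    Raises :class:`DomainError` when no dated record is in scope (the
    fraction would be 0/0).
    """
    records = _scoped(panel, scope, mode)
    dated = [r for r in records if r.year is not None]
    if not dated:
        raise DomainError("no dated records in scope; fraction undefined")
    older = sum(1 for r in dated if r.year < year)
    return FractionBefore(
        cutoff=year,
        fraction=older / len(dated),
        n_dated=len(dated),
        n_undated=len(records) - len(dated),
    )


def staleness_flags(
    panel: FCDBPanel,
    scope: Scope = Scope(),
    max_age_years: int = 20,
    reference_year: int = 2022,
) -> pd.DataFrame:
    """Per-record staleness against a maximum acceptable age.

    Returns a frame with one row per in-scope record (both modes — staleness
    is about the record, not its value) and a ``flag`` column in
    {"stale", "fresh", "unknown-age"}; ``date_is_upper_bound`` marks records
    whose source kind makes the year an upper bound only.
    """
    rows = []
    for rec in (r for r in panel if scope.matches(r)):
        if rec.year is None:
            flag = "unknown-age"
        elif reference_year - rec.year > max_age_years:
            flag = "stale"
        else:
            flag = "fresh"
        rows.append(
            {
                "food_id": rec.food_id,
                "db_id": rec.db_id,
                "component_id": rec.component_id,
                "year": rec.year,
                "flag": flag,
                "date_is_upper_bound": rec.source_kind in DATE_IS_UPPER_BOUND_KINDS,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "food_id",
            "db_id",
            "component_id",
            "year",
            "flag",
            "date_is_upper_bound",
        ],
    )
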