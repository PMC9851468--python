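"""Readers and writers for panel tables, bibliographic corpora, and synonyms.

File formats
------------
Panel: a comma- or tab-delimited table (delimiter auto-detected) with columns
``food_id, db_id, component_id, quantity, unit, status, year, source_kind,
source_ref``. Quantities are converted to g/100 g on load. Legacy tables that
carry only a numeric column (no ``status``) are supported through
:class:`PanelDialect` — the ``zeros_are`` option decides whether a literal
``0`` means an explicit zero or a missing value.

Corpus: JSON lines, one document per line with fields ``doc_id, title,
abstract, year, references``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .errors import IntegrityError, ParseError, UnitError
from .model import (
    UNIT_ALIASES,
    UNITS,
    ComponentValue,
    Document,
    FCDBPanel,
    SourceKind,
    ValueStatus,
)

logger = logging.getLogger(__name__)

PANEL_COLUMNS = (
    "food_id",
    "db_id",
    "component_id",
    "quantity",
    "unit",
    "status",
    "year",
    "source_kind",
    "source_ref",
)

REQUIRED_PANEL_COLUMNS = ("food_id", "db_id", "component_id", "quantity", "unit")


@dataclass(frozen=True)
class PanelDialect:
    """Loader options for panel tables.

    ``zeros_are`` only applies when the file has no ``status`` column: a
    numeric 0 then becomes ``zero_reported`` (default) or ``not_reported``,
    matching how legacy tables conflate the two meanings.
    """

    delimiter: Optional[str] = None  # None = sniff comma vs tab
    zeros_are: str = "zero_reported"

    def __post_init__(self) -> None:
        if self.zeros_are not in ("zero_reported", "not_reported"):
            raise ValueError(f"zeros_are must name a status, got {self.zeros_are!r}")


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _parse_unit(token: str, lineno: int) -> float:
    canonical = UNIT_ALIASES.get(token.strip().lower().replace(" ", ""))
    if canonical is None:
        raise UnitError(f"line {lineno}: unknown unit {token!r}")
    return UNITS[canonical].factor_to_g


def read_panel(path: Union[str, Path], dialect: PanelDialect = PanelDialect()) -> FCDBPanel:
    """Load a delimited panel file into an :class:`FCDBPanel`.

    Every row becomes a :class:`ComponentValue` with the quantity converted
    to g/100 g. Malformed rows raise :class:`ParseError` naming the line,
    unknown units raise :class:`UnitError`, duplicate (food, db, component)
    triples raise :class:`IntegrityError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = dialect.delimiter or _sniff_delimiter(lines[0])
    reader = csv.DictReader(lines, delimiter=delim)
    header = reader.fieldnames or []
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c != "unit" and c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_status = "status" in header
    has_unit = "unit" in header
    records: list[ComponentValue] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            qty_raw = (row.get("quantity") or "").strip()
            factor = _parse_unit(row["unit"], lineno) if has_unit and (row.get("unit") or "").strip() else 1.0
            quantity: Optional[float]
            if qty_raw == "":
                quantity = None
            else:
                quantity = float(qty_raw) * factor
                if math.isnan(quantity):
                    quantity = None
            if has_status and (row.get("status") or "").strip():
                status = ValueStatus((row["status"] or "").strip())
            elif quantity is None:
                status = ValueStatus.NOT_REPORTED
            elif quantity == 0:
                status = ValueStatus(dialect.zeros_are)
                if status is ValueStatus.NOT_REPORTED:
                    quantity = None
            else:
                status = ValueStatus.QUANTIFIED
            year_raw = (row.get("year") or "").strip()
            year = int(float(year_raw)) if year_raw else None
            kind_raw = (row.get("source_kind") or "").strip()
            kind = SourceKind(kind_raw) if kind_raw else SourceKind.UNKNOWN
            ref = (row.get("source_ref") or "").strip() or None
            records.append(
                ComponentValue(
                    food_id=(row.get("food_id") or "").strip(),
                    db_id=(row.get("db_id") or "").strip(),
                    component_id=(row.get("component_id") or "").strip(),
                    status=status,
                    quantity=quantity if status is ValueStatus.QUANTIFIED else (
                        0.0 if status is ValueStatus.ZERO_REPORTED else None
                    ),
                    year=year,
                    source_kind=kind,
                    source_ref=ref,
                )
            )
        except (UnitError, IntegrityError):
            raise
        except (KeyError, ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return FCDBPanel(records)


def write_panel(panel: FCDBPanel, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write a panel in the canonical column order, quantities in g/100 g."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(PANEL_COLUMNS)
        for rec in sorted(panel.records, key=ComponentValue.key):
            writer.writerow(
                [
                    rec.food_id,
                    rec.db_id,
                    rec.component_id,
                    "" if rec.quantity is None else repr(rec.quantity),
                    "g/100g",
                    rec.status.value,
                    "" if rec.year is None else rec.year,
                    rec.source_kind.value,
                    rec.source_ref or "",
                ]
            )


def read_corpus(path: Union[str, Path]) -> list[Document]:
    """Load a JSON-lines corpus.

    Self-citations are dropped with a logged warning; references to documents
    outside the corpus are kept (graph construction filters them later).
    Duplicate ``doc_id`` raises :class:`IntegrityError`; a line without a
    ``doc_id`` raises :class:`ParseError`.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON ({exc})") from exc
            doc_id = obj.get("doc_id")
            if not doc_id:
                raise ParseError(f"{path}: line {lineno}: missing doc_id")
            if doc_id in seen:
                raise IntegrityError(f"{path}: duplicate doc_id {doc_id!r} at line {lineno}")
            seen.add(doc_id)
            refs = list(obj.get("references") or [])
            if doc_id in refs:
                logger.warning("document %r cites itself; self-reference dropped", doc_id)
                refs = [r for r in refs if r != doc_id]
            docs.append(
                Document(
                    doc_id=doc_id,
                    title=obj.get("title") or "",
                    abstract=obj.get("abstract") or "",
                    year=obj.get("year"),
                    references=tuple(refs),
                )
            )
    return docs


def write_corpus(docs: Iterable[Document], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "year": doc.year,
                        "references": list(doc.references),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_synonyms(path: Optional[Union[str, Path]] = None) -> dict[str, str]:
    """Load a raw-label -> canonical-component-id table (TSV, two columns).

    Defaults to the editable table shipped with the package. Lookup keys are
    lower-cased and whitespace-collapsed.
    """
    if path is None:
        source = resources.files("fcdbaudit.data").joinpath("component_synonyms.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")[:2]
        table[" ".join(raw.lower().split())] = canonical
    return table


def harmonize_component(raw_name: str, synonym_table: Mapping[str, str]) -> str:
    """Map a raw component label to a canonical id.

    Unmapped names return a namespaced passthrough id (``raw:<name>``) and
    are logged so compilers can extend the synonym table.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("component name must be non-empty")
    key = " ".join(raw_name.lower().split())
    if key in synonym_table:
        return synonym_table[key]
    logger.info("unmapped component label %r; passing through namespaced", raw_name)
    return f"raw:{raw_name.strip()}"
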