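"""Food x database coverage matrices.

Two counting modes separate "the database says something" from "the database
reports a positive amount":

* ``reported`` — counts records whose status is ``quantified`` or
  ``zero_reported`` (an explicit zero is information);
* ``nonzero``  — counts only ``quantified`` records with quantity > 0.

``not_reported`` records are never counted. The gap between the two modes is
itself diagnostic: databases that pad their tables with assumed zeros look
rich in the first mode and thin in the second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .model import FCDBPanel

__all__ = ["CoverageMatrix", "coverage_matrix", "order_matrix", "coverage_summary"]

MODES = ("reported", "nonzero")


@dataclass
class CoverageMatrix:
    """Food x database grid of component counts under one counting mode."""

    mode: str
    counts: pd.DataFrame  # index = food ids (rows), columns = db ids

    @property
    def row_order(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def col_order(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.counts.to_csv(path, sep="\t", index_label="food_id")

    def summary_json(self, path: Union[str, Path]) -> None:
        row_sums, col_sums = coverage_summary(self)
        Path(path).write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "row_order": list(self.row_order),
                    "col_order": list(self.col_order),
                    "row_sums": row_sums.to_dict(),
                    "col_sums": col_sums.to_dict(),
                },
                indent=2,
            )
        )


def coverage_matrix(panel: FCDBPanel, mode: str) -> CoverageMatrix:
    """Count components per (food, database) under ``mode``.

    An empty panel (or empty declared index sets) yields a zero matrix over
    the declared foods/databases rather than an error.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    counts = pd.DataFrame(
        0, index=list(panel.food_ids), columns=list(panel.db_ids), dtype=int
    )
    for rec in panel:
        hit = rec.is_reported if mode == "reported" else rec.is_nonzero
        if hit:
            counts.loc[rec.food_id, rec.db_id] += 1
    return CoverageMatrix(mode=mode, counts=counts)


def order_matrix(m: CoverageMatrix) -> CoverageMatrix:
    """Sort rows and columns by decreasing marginal sum, ties lexicographic.

    The cell values are unchanged up to permutation, so applying the
    ordering twice is a no-op.
    """
    c = m.counts
    row_key = sorted(c.index, key=lambda i: (-c.loc[i].sum(), i))
    col_key = sorted(c.columns, key=lambda j: (-c[j].sum(), j))
    return CoverageMatrix(mode=m.mode, counts=c.loc[row_key, col_key].copy())


def coverage_summary(m: CoverageMatrix) -> tuple[pd.Series, pd.Series]:
    """Exact marginal sums: (per-food row sums, per-database column sums)."""
    return m.counts.sum(axis=1), m.counts.sum(axis=0)
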