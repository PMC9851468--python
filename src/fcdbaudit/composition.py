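"""Composition quality control and cross-database comparison.

A fat that is essentially 100% lipid should have fatty-acid classes (plus
minor unsaponifiables) summing to at most 100 g per 100 g. Profiles compiled
from heterogeneous publications routinely violate this: sums overshoot 100 g,
or fall short by an unexplained residual of "other compounds". The checks in
this module quantify those pathologies, compare the same component across
databases, flag suspiciously identical values (a signature of borrowing),
detect bimodal sample pools hiding behind a single average, and recognise
composite values formed by averaging two different foods.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import DomainError, ScopeError
from .model import FATTY_ACID_CLASS_IDS, FCDBPanel, ValueStatus, fatty_acid_class

__all__ = [
    "MassBalanceReport",
    "DiscrepancyReport",
    "HeterogeneityReport",
    "MixtureReport",
    "resolve_class_components",
    "mass_balance",
    "relative_difference",
    "cross_source_agreement",
    "scan_cross_source",
    "sample_heterogeneity",
    "mixture_average_check",
]

#: Two values closer than this (in g/100 g) count as "identical" for the
#: borrowing-suspicion check; chosen to catch copies surviving rounding.
EPS_IDENTICAL_DEFAULT = 0.005


@dataclass(frozen=True)
class MassBalanceReport:
    """Class-wise sum against the 100 g budget for one (food, database)."""

    food_id: str
    db_id: str
    class_sum: float
    residual: float              #: 100 - class_sum; negative = overshoot
    overshoot: bool
    components_used: tuple[str, ...]
    tolerance: float = 0.0


def resolve_class_components(
    panel: FCDBPanel,
    food_id: str,
    db_id: str,
    classes: Sequence[str] = FATTY_ACID_CLASS_IDS,
) -> set[str]:
    """Pick the component ids to sum for a fatty-acid mass balance.

    For each class (SFA/MUFA/PUFA/TFA): use the quantified class aggregate
    when the database reports one, otherwise fall back to the quantified
    leaf fatty acids belonging to that class — never both, so members are
    not double-counted with their aggregate.
    """
    records = panel.select(foods=[food_id], dbs=[db_id])
    quantified = {r.component_id for r in records if r.status is ValueStatus.QUANTIFIED}
    chosen: set[str] = set()
    for cls in classes:
        if cls in quantified:
            chosen.add(cls)
        else:
            chosen.update(c for c in quantified if fatty_acid_class(c) == cls)
    return chosen


def mass_balance(
    panel: FCDBPanel,
    food_id: str,
    db_id: str,
    component_class: Optional[Sequence[str]] = None,
    tolerance: float = 0.0,
) -> MassBalanceReport:
    """Sum a component class for one (food, database) against 100 g.

    ``component_class`` lists the ids to sum (they must not mix a class
    aggregate with its own members; use :func:`resolve_class_components`,
    the default, to guarantee that). Only ``quantified`` records enter the
    sum. ``residual = 100 - class_sum`` exactly; ``overshoot`` iff
    ``class_sum > 100 + tolerance``.
    """
    if food_id not in panel.food_ids or db_id not in panel.db_ids:
        raise ScopeError(f"({food_id!r}, {db_id!r}) not present in panel")
    if component_class is None:
        ids = resolve_class_components(panel, food_id, db_id)
    else:
        ids = set(component_class)
        for cls in FATTY_ACID_CLASS_IDS:
            members = {c for c in ids if fatty_acid_class(c) == cls}
            if cls in ids and members:
                raise DomainError(
                    f"component class mixes aggregate {cls} with members {sorted(members)}"
                )
    used = []
    total = 0.0
    for comp in sorted(ids):
        rec = panel.get(food_id, db_id, comp)
        if rec is not None and rec.status is ValueStatus.QUANTIFIED:
            total += rec.quantity  # type: ignore[operator]
            used.append(comp)
    return MassBalanceReport(
        food_id=food_id,
        db_id=db_id,
        class_sum=total,
        residual=100.0 - total,
        overshoot=total > 100.0 + tolerance,
        components_used=tuple(used),
        tolerance=tolerance,
    )


def relative_difference(a: float, b: float) -> float:
    """Signed relative difference ``(a - b) / b`` against baseline ``b`` > 0.

    This is the "X% higher" convention: the reference value is the
    denominator, so the statistic is not symmetric in its arguments.
    """
    if b <= 0:
        raise DomainError(f"baseline must be positive, got {b}")
    return (a - b) / b


@dataclass(frozen=True)
class DiscrepancyReport:
    """Cross-database agreement for one component of one food."""

    component_id: str
    values: dict[str, float]
    max_pairwise_reldiff: float
    suspicious_shared_source: bool
    eps_identical: float = EPS_IDENTICAL_DEFAULT


def cross_source_agreement(
    values: Mapping[str, float],
    component_id: str = "",
    eps_identical: float = EPS_IDENTICAL_DEFAULT,
) -> DiscrepancyReport:
    """Compare one component's quantities across databases.

    ``max_pairwise_reldiff`` is ``max over pairs of |a - b| / min(a, b)``
    (symmetric, baseline = smaller value). ``suspicious_shared_source`` is
    true when *all* values agree pairwise within ``eps_identical`` — too
    close for independent analyses, the signature of a shared or copied
    source.
    """
    if len(values) < 2:
        raise ScopeError("cross-source agreement needs values from >= 2 databases")
    vals = dict(values)
    max_rd = 0.0
    all_identical = True
    for (da, a), (db, b) in itertools.combinations(sorted(vals.items()), 2):
        lo = min(a, b)
        if lo <= 0:
            raise DomainError(
                f"non-positive quantity for {da!r}/{db!r}; relative spread undefined"
            )
        max_rd = max(max_rd, abs(a - b) / lo)
        if abs(a - b) > eps_identical:
            all_identical = False
    return DiscrepancyReport(
        component_id=component_id,
        values=vals,
        max_pairwise_reldiff=max_rd,
        suspicious_shared_source=all_identical,
        eps_identical=eps_identical,
    )


def scan_cross_source(
    panel: FCDBPanel,
    food_id: str,
    component_id: str,
    eps_identical: float = EPS_IDENTICAL_DEFAULT,
) -> DiscrepancyReport:
    """Run :func:`cross_source_agreement` on a panel's quantified values."""
    values = {
        r.db_id: r.quantity
        for r in panel.select(foods=[food_id], components=[component_id])
        if r.status is ValueStatus.QUANTIFIED and (r.quantity or 0.0) > 0
    }
    return cross_source_agreement(values, component_id=component_id, eps_identical=eps_identical)


@dataclass(frozen=True)
class HeterogeneityReport:
    """Bimodality check for a pool of individual sample values.

    The sorted samples are split at the single largest adjacent gap; when
    the two cluster means differ by more than the threshold, the pooled
    mean is an average over heterogeneous material (e.g. conventional and
    high-oleic cultivars pooled into one figure).
    """

    samples: tuple[float, ...]
    pooled_mean: float
    split_gap: float
    cluster_means: tuple[float, float]
    heterogeneous: bool
    note: str = ""


def sample_heterogeneity(
    samples: Sequence[float], gap_threshold: float = 25.0
) -> HeterogeneityReport:
    """Split samples at the largest adjacent gap and compare cluster means."""
    vals = tuple(float(s) for s in samples)
    if len(vals) < 2:
        mean = vals[0] if vals else float("nan")
        return HeterogeneityReport(
            samples=vals,
            pooled_mean=mean,
            split_gap=0.0,
            cluster_means=(mean, mean),
            heterogeneous=False,
            note="insufficient-samples",
        )
    s = sorted(vals)
    gaps = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    cut = max(range(len(gaps)), key=lambda i: (gaps[i], -i))  # first largest gap
    lower, upper = s[: cut + 1], s[cut + 1 :]
    m_lo, m_hi = statistics.fmean(lower), statistics.fmean(upper)
    return HeterogeneityReport(
        samples=vals,
        pooled_mean=statistics.fmean(vals),
        split_gap=gaps[cut],
        cluster_means=(m_lo, m_hi),
        heterogeneous=abs(m_hi - m_lo) > gap_threshold,
    )


@dataclass(frozen=True)
class MixtureReport:
    """Result of testing whether a value is a composite of two foods."""

    observed: float
    flagged: bool
    pair: Optional[tuple[str, str]] = None
    pair_statistic: Optional[float] = None
    statistic: str = "mean"


def mixture_average_check(
    observed: float,
    candidates: Mapping[str, float],
    eps: float = 0.5,
    statistic: str = "mean",
) -> MixtureReport:
    """Detect a value formed by pooling two different foods.

    Flags when ``observed`` lies within ``eps`` of ``statistic`` (mean or
    median) of some cross-food pair while differing from every single
    candidate by more than ``eps``. With fewer than two candidates nothing
    can be flagged.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    stat = statistics.fmean if statistic == "mean" else statistics.median
    if len(candidates) < 2:
        return MixtureReport(observed=observed, flagged=False, statistic=statistic)
    if any(abs(observed - v) <= eps for v in candidates.values()):
        return MixtureReport(observed=observed, flagged=False, statistic=statistic)
    best: Optional[tuple[str, str]] = None
    best_stat: Optional[float] = None
    for (fa, va), (fb, vb) in itertools.combinations(sorted(candidates.items()), 2):
        value = stat([va, vb])
        if abs(observed - value) <= eps and (
            best_stat is None or abs(observed - value) < abs(observed - best_stat)
        ):
            best, best_stat = (fa, fb), value
    return MixtureReport(
        observed=observed,
        flagged=best is not None,
        pair=best,
        pair_statistic=best_stat,
        statistic=statistic,
    )
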