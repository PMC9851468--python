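"""Seeded generators for FCDB panels and citation corpora with known truth.

Real food-composition databases and bibliographic snapshots cannot ship with
the package, so these generators emulate their structure — sparse food x
component coverage with zero-inflation, decade-structured acquisition dates,
verbatim value borrowing between databases, fatty-acid profiles that may
overshoot the 100 g budget, and a citation corpus with planted communities
whose documents over-express a community signature term.

Every planted pathology is recorded in a :class:`Ledger` *as it is emitted*,
so the audits can be tested against an oracle that does not share their code
path: coverage counts, decade tallies, borrow pairs, overshoot profiles and
the planted community assignment are all ledger entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigError
from .model import ComponentValue, Document, FCDBPanel, SourceKind, ValueStatus, fatty_acid_class

logger = logging.getLogger(__name__)

__all__ = ["PanelConfig", "CorpusConfig", "Ledger", "generate_panel", "generate_corpus"]

OIL_NAMES = (
    "palm",
    "palm_kernel",
    "sunflower",
    "olive",
    "coconut",
    "soybean",
    "rapeseed",
    "peanut",
    "cottonseed",
)

CLASS_AGGREGATES = ("SFA", "MUFA", "PUFA")
LEAF_FATTY_ACIDS = ("FA12:0", "FA14:0", "FA16:0", "FA18:0", "FA18:1", "FA18:2", "FA18:3")
MICRO_COMPONENTS = ("vitamin_e", "vitamin_k1", "water")


def load_oil_profiles() -> dict:
    """The illustrative reference fatty-acid profiles shipped as data."""
    text = resources.files("fcdbaudit.data").joinpath("oil_profiles.json").read_text("utf-8")
    profiles = json.loads(text)
    profiles.pop("_comment", None)
    return profiles


def _default_decade_weights(n_dbs: int) -> list[dict[int, float]]:
    """Per-database decade mixes: some databases old, some current."""
    presets = [
        {1970: 0.40, 1980: 0.20, 2000: 0.30, 2010: 0.10},       # legacy-heavy
        {2000: 0.80, 2010: 0.20},                                 # one-shot compilation
        {1990: 0.30, 2000: 0.35, 2010: 0.35},                     # decadal updates
        {2010: 0.60, 2020: 0.40},                                 # recent
    ]
    return [presets[i % len(presets)] for i in range(n_dbs)]


@dataclass
class PanelConfig:
    """Study conditions for the synthetic multi-database panel.

    Defaults emulate a half-dozen vegetable oils audited across four
    databases of very different vintage and completeness: ~70% of cells
    carry some value, a quarter of non-fatty-acid values are explicit
    zeros, a tenth of values are borrowed verbatim from a sibling
    database, and a tenth of fatty-acid profiles overshoot 100 g.
    """

    n_foods: int = 6
    n_dbs: int = 4
    n_components: int = 16
    coverage_prob: Union[float, Sequence[float]] = 0.7
    zero_prob: Union[float, Sequence[float]] = 0.25
    decade_weights: Optional[Sequence[dict[int, float]]] = None
    undated_prob: float = 0.1
    borrow_prob: float = 0.1
    overshoot_rate: float = 0.1
    dirichlet_alpha: float = 300.0
    seed: int = 0

    def per_db(self, value: Union[float, Sequence[float]]) -> list[float]:
        if isinstance(value, (int, float)):
            return [float(value)] * self.n_dbs
        vals = [float(v) for v in value]
        if len(vals) != self.n_dbs:
            raise ConfigError(f"expected {self.n_dbs} per-db values, got {len(vals)}")
        return vals

    def validate(self) -> None:
        if min(self.n_foods, self.n_dbs, self.n_components) < 1:
            raise ConfigError("n_foods, n_dbs, n_components must be >= 1")
        for name in ("coverage_prob", "zero_prob"):
            for p in self.per_db(getattr(self, name)):
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name in ("undated_prob", "borrow_prob", "overshoot_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.dirichlet_alpha <= 0:
            raise ConfigError("dirichlet_alpha must be positive")
        weights = self.decade_weights or _default_decade_weights(self.n_dbs)
        for i, w in enumerate(weights):
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"decade_weights[{i}] sum to {total}, not 1")
            if any(d % 10 != 0 for d in w):
                raise ConfigError(f"decade_weights[{i}] keys must be decade starts")


@dataclass
class CorpusConfig:
    """Study conditions for the planted-community citation corpus."""

    k: int = 4
    docs_per_community: int = 50
    p_in: float = 0.20
    p_out: float = 0.005
    signature_boost: float = 8.0
    vocab_size: int = 500
    doc_length: int = 60
    filter_terms: tuple[str, ...] = ("palm", "oil")
    zipf_exponent: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1 or self.docs_per_community < 1:
            raise ConfigError("k and docs_per_community must be >= 1")
        if not (0.0 <= self.p_out <= 1.0 and 0.0 <= self.p_in <= 1.0):
            raise ConfigError("p_in and p_out must lie in [0, 1]")
        if self.p_in <= self.p_out:
            logger.warning(
                "p_in (%s) <= p_out (%s): community recovery is not expected",
                self.p_in,
                self.p_out,
            )
        if self.doc_length < 3:
            raise ConfigError("doc_length must be >= 3 (trigram extraction)")
        if self.signature_boost < 0:
            raise ConfigError("signature_boost must be non-negative")


@dataclass
class Ledger:
    """Ground truth describing exactly what a generator emitted."""

    # panel side
    coverage: dict[str, dict[tuple[str, str], int]] = field(
        default_factory=lambda: {"reported": {}, "nonzero": {}}
    )
    decades: dict[str, dict[str, dict[int, int]]] = field(
        default_factory=lambda: {"reported": {}, "nonzero": {}}
    )
    undated: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"reported": {}, "nonzero": {}}
    )
    borrow_pairs: list[tuple[str, str, str, str]] = field(default_factory=list)
    overshoot: dict[tuple[str, str], float] = field(default_factory=dict)
    food_profiles: dict[str, str] = field(default_factory=dict)
    # corpus side
    community_of: dict[str, int] = field(default_factory=dict)
    signature_terms: dict[int, str] = field(default_factory=dict)
    edge_stats: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        def _keyed(d):  # tuple keys -> "a|b" strings for JSON
            return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in d.items()}

        payload = {
            "coverage": {m: _keyed(v) for m, v in self.coverage.items()},
            "decades": self.decades,
            "undated": self.undated,
            "borrow_pairs": self.borrow_pairs,
            "overshoot": _keyed(self.overshoot),
            "food_profiles": self.food_profiles,
            "community_of": self.community_of,
            "signature_terms": self.signature_terms,
            "edge_stats": self.edge_stats,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _tally(ledger: Ledger, mode: str, food: str, db: str) -> None:
    key = (food, db)
    ledger.coverage[mode][key] = ledger.coverage[mode].get(key, 0) + 1


def _tally_decade(ledger: Ledger, mode: str, db: str, year: Optional[int]) -> None:
    if year is None:
        ledger.undated[mode][db] = ledger.undated[mode].get(db, 0) + 1
    else:
        decade = (year // 10) * 10
        bins = ledger.decades[mode].setdefault(db, {})
        bins[decade] = bins.get(decade, 0) + 1


def generate_panel(config: PanelConfig) -> tuple[FCDBPanel, Ledger]:
    """Generate a multi-database panel plus its ground-truth ledger.

    Deterministic for a fixed ``config.seed`` (byte-identical reruns).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = load_oil_profiles()
    coverage_p = config.per_db(config.coverage_prob)
    zero_p = config.per_db(config.zero_prob)
    decade_weights = list(config.decade_weights or _default_decade_weights(config.n_dbs))

    foods = [f"food{i:02d}" for i in range(config.n_foods)]
    dbs = [f"db{i:02d}" for i in range(config.n_dbs)]
    base = list(CLASS_AGGREGATES) + list(LEAF_FATTY_ACIDS) + list(MICRO_COMPONENTS)
    if config.n_components <= len(base):
        components = base[: config.n_components]
    else:
        components = base + [f"comp{i:03d}" for i in range(config.n_components - len(base))]

    ledger = Ledger()
    food_oil = {f: OIL_NAMES[i % len(OIL_NAMES)] for i, f in enumerate(foods)}
    ledger.food_profiles = dict(food_oil)

    # plant the overshoot set up front
    all_pairs = [(f, d) for f in foods for d in dbs]
    n_over = int(round(config.overshoot_rate * len(all_pairs)))
    over_idx = rng.choice(len(all_pairs), size=n_over, replace=False) if n_over else []
    overshoot_pairs = {all_pairs[i] for i in np.sort(over_idx)}

    # ---- plan quantities -------------------------------------------------
    planned: dict[tuple[str, str, str], dict] = {}
    for food in foods:
        oil = profiles[food_oil[food]]
        ref_fracs = np.array([oil["class_fractions"].get(c, 0.0) for c in CLASS_AGGREGATES])
        for di, db in enumerate(dbs):
            fracs = rng.dirichlet(config.dirichlet_alpha * np.maximum(ref_fracs, 1e-3))
            if (food, db) in overshoot_pairs:
                fa_total = float(rng.uniform(100.2, 101.2))
            else:
                fa_total = float(np.clip(oil["fa_total"] * (1 + rng.normal(0, 0.01)), 90, 99.5))
            class_amount = dict(zip(CLASS_AGGREGATES, fracs * fa_total))
            if (food, db) in overshoot_pairs:
                ledger.overshoot[(food, db)] = sum(class_amount.values())
            leaf_amount: dict[str, float] = {}
            for cls in CLASS_AGGREGATES:
                leaves = [
                    l for l in LEAF_FATTY_ACIDS
                    if fatty_acid_class(l) == cls and oil["leaf_weights"].get(l, 0) > 0
                ]
                weights = np.array([oil["leaf_weights"][l] for l in leaves], dtype=float)
                if len(leaves):
                    weights = weights / weights.sum()
                    for l, w in zip(leaves, weights):
                        leaf_amount[l] = class_amount[cls] * float(w)
            for comp in components:
                forced = comp in CLASS_AGGREGATES and (food, db) in overshoot_pairs
                covered = forced or bool(rng.random() < coverage_p[di])
                if not covered:
                    planned[(food, db, comp)] = {"status": ValueStatus.NOT_REPORTED}
                    continue
                if comp in CLASS_AGGREGATES:
                    planned[(food, db, comp)] = {
                        "status": ValueStatus.QUANTIFIED,
                        "quantity": class_amount[comp],
                    }
                elif comp in LEAF_FATTY_ACIDS:
                    if comp in leaf_amount:
                        planned[(food, db, comp)] = {
                            "status": ValueStatus.QUANTIFIED,
                            "quantity": leaf_amount[comp],
                        }
                    else:
                        planned[(food, db, comp)] = {"status": ValueStatus.ZERO_REPORTED}
                else:
                    if rng.random() < zero_p[di]:
                        planned[(food, db, comp)] = {"status": ValueStatus.ZERO_REPORTED}
                    else:
                        planned[(food, db, comp)] = {
                            "status": ValueStatus.QUANTIFIED,
                            "quantity": float(rng.lognormal(mean=-3.0, sigma=1.0)),
                        }

    # ---- plant verbatim borrowing ---------------------------------------
    for food in foods:
        for comp in components:
            donors = [
                d for d in dbs
                if planned[(food, d, comp)]["status"] is ValueStatus.QUANTIFIED
            ]
            if len(donors) < 2:
                continue
            # decide borrowers first; donors are the remaining originals, so a
            # borrowed quantity always traces back to a real measurement;
            # planted overshoot profiles keep their own class aggregates
            borrowers = [
                db for db in donors
                if rng.random() < config.borrow_prob
                and not (comp in CLASS_AGGREGATES and (food, db) in overshoot_pairs)
            ]
            originals = [db for db in donors if db not in borrowers]
            if not originals:
                continue
            for db in borrowers:
                donor = originals[int(rng.integers(len(originals)))]
                planned[(food, db, comp)]["quantity"] = planned[(food, donor, comp)][
                    "quantity"
                ]
                planned[(food, db, comp)]["borrowed_from"] = donor
                ledger.borrow_pairs.append((food, comp, donor, db))

    # ---- assign dates and emit records ----------------------------------
    year_of: dict[tuple[str, str, str], Optional[int]] = {}

    def draw_year(di: int) -> Optional[int]:
        if rng.random() < config.undated_prob:
            return None
        w = decade_weights[di]
        decades = sorted(w)
        probs = np.array([w[d] for d in decades])
        decade = decades[int(rng.choice(len(decades), p=probs / probs.sum()))]
        return int(decade + rng.integers(0, 10))

    records: list[ComponentValue] = []
    # donors (non-borrowed) first so borrowers can inherit the donor's year
    keys = sorted(planned)
    for key in keys:
        if "borrowed_from" not in planned[key] and planned[key]["status"] is not ValueStatus.NOT_REPORTED:
            year_of[key] = draw_year(dbs.index(key[1]))
    for key in keys:
        plan = planned[key]
        if "borrowed_from" in plan:
            year_of[key] = year_of[(key[0], plan["borrowed_from"], key[2])]

    source_kinds = (SourceKind.DIRECT_ANALYSIS, SourceKind.LITERATURE, SourceKind.COMPILED)
    for key in keys:
        food, db, comp = key
        plan = planned[key]
        status = plan["status"]
        if status is ValueStatus.NOT_REPORTED:
            records.append(
                ComponentValue(food, db, comp, status=status, source_kind=SourceKind.UNKNOWN)
            )
            continue
        year = year_of[key]
        if "borrowed_from" in plan:
            kind = SourceKind.BORROWED
            ref = plan["borrowed_from"]
        else:
            kind = source_kinds[int(rng.choice(3, p=[0.3, 0.5, 0.2]))]
            ref = None
        quantity = plan.get("quantity") if status is ValueStatus.QUANTIFIED else 0.0
        rec = ComponentValue(
            food, db, comp, status=status, quantity=quantity, year=year,
            source_kind=kind, source_ref=ref,
        )
        records.append(rec)
        _tally(ledger, "reported", food, db)
        _tally_decade(ledger, "reported", db, year)
        if rec.is_nonzero:
            _tally(ledger, "nonzero", food, db)
            _tally_decade(ledger, "nonzero", db, year)

    panel = FCDBPanel(records, food_ids=foods, db_ids=dbs, component_ids=components)
    return panel, ledger


def generate_corpus(config: CorpusConfig) -> tuple[list[Document], Ledger]:
    """Generate a planted-community citation corpus plus its ledger.

    Each document's text is a draw from a long-tail (Zipf-like) background
    vocabulary mixed with its community's signature term (weighted at
    ``signature_boost`` times the most frequent background word), with the
    corpus filter terms prepended to every title so the whole corpus passes
    its own keyword filter. Citations follow a planted-partition model:
    within-community pairs link with ``p_in``, across with ``p_out``; the
    higher-indexed document carries the reference.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.k * config.docs_per_community
    doc_ids = [
        f"d{c:02d}_{i:03d}"
        for c in range(config.k)
        for i in range(config.docs_per_community)
    ]
    community = {
        doc_ids[j]: j // config.docs_per_community for j in range(n)
    }

    background = [f"w{i:04d}" for i in range(config.vocab_size)]
    bg_probs = np.arange(1, config.vocab_size + 1, dtype=float) ** (-config.zipf_exponent)
    bg_probs /= bg_probs.sum()
    signature = {c: f"topic{c:02d}sig" for c in range(config.k)}

    ledger = Ledger()
    ledger.community_of = dict(community)
    ledger.signature_terms = dict(signature)

    texts: dict[str, list[str]] = {}
    for doc_id in doc_ids:
        c = community[doc_id]
        words = background + [signature[c]]
        probs = np.append(bg_probs, config.signature_boost * bg_probs[0])
        probs = probs / probs.sum()
        idx = rng.choice(len(words), size=config.doc_length, p=probs)
        texts[doc_id] = [words[i] for i in idx]

    refs: dict[str, list[str]] = {d: [] for d in doc_ids}
    e_in = e_out = poss_in = poss_out = 0
    for a in range(n):
        for b in range(a + 1, n):
            same = community[doc_ids[a]] == community[doc_ids[b]]
            p = config.p_in if same else config.p_out
            poss_in, poss_out = poss_in + same, poss_out + (not same)
            if rng.random() < p:
                refs[doc_ids[b]].append(doc_ids[a])
                e_in, e_out = e_in + same, e_out + (not same)
    ledger.edge_stats = {
        "edges_in": e_in,
        "edges_out": e_out,
        "possible_in": poss_in,
        "possible_out": poss_out,
    }

    docs = []
    for doc_id in doc_ids:
        tokens = texts[doc_id]
        title = " ".join(list(config.filter_terms) + tokens[:5])
        abstract = " ".join(tokens[5:])
        docs.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                year=int(rng.integers(1980, 2021)),
                references=tuple(refs[doc_id]),
            )
        )
    return docs, ledger
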