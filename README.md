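# fcdbaudit

Audit toolkit for **food composition databases (FCDBs)** — the national and
international tables that report, for each food, the quantity of every
nutrient and biochemical component per 100 g of edible portion — plus a
**literature-mapping arm** that organises a scientific corpus into citation
communities with automatically ranked keyword labels.

It is aimed at nutrition informaticians and database compilers who need to
answer questions such as: *how much of this table is explicit zeros rather
than measurements? how old is the information behind each value? do the
fatty-acid profiles even add up to 100 g? do two databases agree because the
food is similar — or because one copied the other?*

## What it computes

**Panel audits.** A panel is a set of `(food, database, component)` records,
each with a three-way status (`quantified` / `zero_reported` /
`not_reported`), a quantity in g/100 g, an optional year, and a source kind.

* *Coverage* — food × database matrices counting components per cell in two
  modes: `reported` (any asserted value, zeros included) and `nonzero`
  (strictly positive quantities only), with rows/columns ordered by
  decreasing marginal sums.
* *Data age* — decade histograms of record years, the fraction of dated
  values collected before a cutoff year, and per-record staleness flags.
  Dates on literature/compiled/borrowed values are treated as upper bounds
  on the measurement date and every report says so.
* *Composition QC* — fatty-acid mass balance per `(food, database)`:
  `class_sum = SFA + MUFA + PUFA (+ trans)`, `residual = 100 − class_sum`
  (the "other compounds" needed to reach 100 g; negative residual = an
  overshooting, internally inconsistent profile). Cross-database agreement
  uses the symmetric relative spread `max |a−b| / min(a,b)` over all pairs
  and flags all-identical value sets as *suspicious shared source*
  (borrowing). Further checks detect bimodal sample pools hidden behind one
  average and composite values formed by averaging two different foods.
* *Literature map* — token-exact keyword filtering of a corpus, an
  undirected citation graph (edge when either document cites the other,
  within the filtered set), removal of degree-0 nodes, in-repo greedy
  modularity (Louvain-family) community detection with seeded restarts and
  Kernighan–Lin refinement, communities labeled A, B, C, … by size, and
  per-community n-gram **importance** scores:
  `importance(g) = freq_in(g) − freq_out(g)` with frequencies normalized by
  the total n-gram count of the document set (per n).

Because the real external databases and bibliographic snapshots cannot ship
with the package, `fcdbaudit.synth` generates panels and citation corpora
with the same pathologies — zero-inflation, decade-structured dates,
verbatim borrowing, >100 g profiles, planted communities and signature
terms — together with a **ledger** recording exactly what was planted, so
every audit can be verified against ground truth.

## Worked example

```python
>>> from fcdbaudit import (ComponentValue, FCDBPanel, ValueStatus,
...                        mass_balance, cross_source_agreement)
>>> panel = FCDBPanel([
...     ComponentValue("palm_oil", "dbX", "SFA",  ValueStatus.QUANTIFIED, 49.94),
...     ComponentValue("palm_oil", "dbX", "MUFA", ValueStatus.QUANTIFIED, 40.00),
...     ComponentValue("palm_oil", "dbX", "PUFA", ValueStatus.QUANTIFIED, 11.00),
... ])
>>> rep = mass_balance(panel, "palm_oil", "dbX")
>>> round(rep.class_sum, 2), round(rep.residual, 2), rep.overshoot
(100.94, -0.94, True)
```

The fatty-acid classes sum to 100.94 g per 100 g of oil — 0.94 g more mass
than the food contains, so the profile is flagged as inconsistent.

```python
>>> rep = cross_source_agreement({"dbX": 43.50, "dbY": 43.68, "dbZ": 43.04})
>>> round(rep.max_pairwise_reldiff, 4), rep.suspicious_shared_source
(0.0149, False)
```

Three databases report palmitic acid within 1.5% of each other — close, but
not identical to the 0.005 g tolerance that would suggest copied values.

End-to-end on synthetic data, from the shell:

```bash
fcdb-audit simulate --seed 7 --out-dir out      # panel.tsv, corpus.jsonl + ledgers
fcdb-audit coverage --panel out/panel.tsv --out-dir out
fcdb-audit report --seed 7 --out-dir out        # the whole pipeline
```

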