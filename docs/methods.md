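# Methods

This note documents the statistical and algorithmic choices behind
`fcdbaudit`: what each audit computes, what the synthetic generators do and
do not emulate, and where the design was genuinely open.

## 1. The panel data model

A panel is a collection of `(food, database, component)` records. The core
modelling decision is the explicit three-way value status:

* `quantified` — the database asserts an amount ≥ 0 (in g/100 g after unit
  harmonization);
* `zero_reported` — the database asserts an explicit zero. This covers
  "measured and absent", "below detection limit" and "assumed absent";
  the sources themselves rarely distinguish these, so the model does not
  try to subdivide further;
* `not_reported` — no value at all.

Most published tables conflate the last two. The loader therefore accepts a
`zeros_are` dialect option (`zero_reported`, the default, or `not_reported`)
for legacy numeric-only tables, making the ambiguity an explicit, audited
choice rather than a silent one. Quantities are normalized to g/100 g on
load (supported units: g, mg, µg per 100 g; the conversion is a single
float multiplication, exact to 1 ulp). Borrowed values are a *source kind*
recorded in the data, not something inferred at load time; inference of
suspicious agreement is the composition audit's job.

Component identifiers use class tags (`SFA`, `MUFA`, `PUFA`, `TFA`) plus
`FA<C>:<D>` notation for leaf fatty acids (`FA16:0` = palmitic acid). The
raw-label → canonical-id synonym table ships as an editable data file.

## 2. Coverage

"The database provides some information" is interpreted as
`status ≠ not_reported`: an explicit zero is information. The `nonzero`
mode keeps only strictly positive quantified values. The gap between the
two modes is diagnostic — tables padded with assumed zeros look rich in
`reported` and thin in `nonzero`. Rows and columns are ordered by
decreasing marginal sums; ties break lexicographically by identifier (the
ordering needs *some* deterministic rule and identifiers are the only
universally available key). An alternative reading — counting components a
database lists with no value at all — is possible but not implemented,
since such rows carry no information under either mode.

## 3. Data age

Records are binned by decade (`[Y, Y+10)`, labeled by the start year).
Undated records are counted separately, never imputed — no defensible
imputation rule exists for compilation dates. `fraction_before(cutoff)`
is computed over *dated* records only, pooling records rather than
weighting databases equally (the pooled convention is documented on the
result object via `n_dated`/`n_undated`). For values sourced from
literature, compilations or borrowing, the attached year is an upper bound
on the measurement date: a compilation published in 2004 may contain
measurements decades older. Every profile carries this caveat, and
staleness flags expose a per-record `date_is_upper_bound` marker.

## 4. Composition quality control

**Mass balance.** For a fat that is essentially 100% lipid, the fatty-acid
classes plus minor unsaponifiable matter must fit in 100 g. The audit sums
`quantified` records over a component class and reports
`residual = 100 − class_sum` exactly; `overshoot ⇔ class_sum > 100 +
tolerance` with tolerance defaulting to 0 g (any overshoot is an
inconsistency; the tolerance is configurable for databases with known
rounding conventions). When a database reports both a class aggregate and
its member fatty acids, the aggregate wins and the members are excluded —
never both, avoiding double counting. The default class set is
SFA + MUFA + PUFA + trans; whether reference tables include trans in their
totals varies, so the set is configurable rather than asserted.

**Cross-source agreement.** The spread statistic is
`max over pairs |a − b| / min(a, b)` — symmetric, with the smaller value as
baseline, matching the "X% higher" convention used when comparing a value
against a reference. `suspicious_shared_source` is true when *all* values
agree pairwise within `ε_identical = 0.005` g/100 g: independent chemical
analyses of a natural product essentially never agree to 5 mg, so such
agreement indicates a copied (borrowed) value surviving rounding. The ε is
a package default, configurable per call.

**Sample heterogeneity.** Sorted samples are split at the single largest
adjacent gap; the pool is heterogeneous when the two cluster means differ
by more than the threshold. This is a bimodality check, not a general
clustering — it targets the common failure mode of pooling two cultivars
(e.g. conventional and high-oleic sunflower) into one average, and will
not resolve three or more modes. Known limitation, by design.

**Mixture averages.** A composite value is flagged when it lies within ε
of the mean (or median) of some cross-food pair of candidate profiles
while lying farther than ε from every single candidate. With two
candidates, mean and median coincide; both statistics are offered because
compilers aggregate either way.

## 5. Literature mapping

**Filtering** is token-exact after lower-casing and punctuation stripping:
"palmitic" does not match the token "palm". Substring matching would
silently inflate any keyword-filtered corpus; the choice is prominent
because it changes corpus sizes materially.

**Graph.** Documents are nodes; an undirected edge joins two documents of
the filtered corpus when *either* reference list contains the other.
Requiring mutual citation would shred the network (mutual citation is
rare); the either-direction reading is an interpretation, recorded here.
References to documents outside the corpus are kept at load and ignored at
graph-build time, so one corpus file can serve many subset analyses.
Degree-0 nodes are removed (the default), rather than extracting the
largest connected component; both operations are available.

**Community detection** is greedy modularity maximization of the Louvain
family, implemented in the package: seeded local moving + graph
aggregation, followed by two refinement stages — unrestricted single-node
moves (a node may join any community or found a new one, not just a
neighbor's) and greedy community merges — plus a Kernighan–Lin pass that
chains globally best single-node moves, tolerating temporary losses, and
keeps the best prefix. Four seeded restarts are run and the
highest-modularity partition wins. The refinements exist because pure
greedy local moving demonstrably stalls below the optimum on small graphs;
with them, the detector matches exhaustive set-partition search on an
enumerated suite of ≤ 8-node graphs (verified in the test suite and the
acceptance script). The KL pass is skipped above 2 000 nodes, where its
O(n²k) cost dominates and local optima are less consequential. The
resolution parameter (default 1.0) trades community size against count.
Determinism: identical graph + seed ⇒ identical partition. Note that the
detector is still a heuristic: nothing guarantees the global optimum on
large graphs, and a different published implementation with different
tie-breaks will generally return a different (equally valid) partition.
Communities are labeled A, B, C, … by decreasing size, ties broken by the
smallest member id.

**Keyword importance.** For community C and n-gram g,
`importance(g) = freq_in(g) − freq_out(g)`, where `freq_in` normalizes g's
count by the total n-gram count (same n) over C's documents and `freq_out`
does the same over all other communities' documents. Normalization is per
n — unigram frequencies against unigram totals, bigrams against bigrams —
and the rankings are merged; pooling all n into one denominator is a
documented alternative the package does not default to, because it lets
abundant unigrams swamp longer grams. Consequence (asserted in tests): for
every n the importances over the union vocabulary sum to zero. N-grams
containing a stopword are dropped entirely (the shipped English stopword
list is editable data). Ranking ties break lexicographically for
determinism.

## 6. Synthetic generators and what they show

`generate_panel` emits, per `(food, database, component)`: a coverage draw
(per-database probability, default 0.7), an explicit-zero draw for
non-fatty-acid components (default 0.25), fatty-acid profiles drawn as
Dirichlet perturbations (concentration 300) around illustrative reference
oil profiles shipped as data, per-database decade mixes for record years
(default presets range from legacy-heavy to current), a 10% undated rate,
verbatim borrowing between databases (default 10%, always traceable to a
non-borrowed donor, inheriting the donor's year), and planted >100 g
profiles (default 10% of cells, forced to sum to 100.2–101.2 g). Every
draw is tallied into a ledger *at emission time* — the ledger is written
by construction, not by re-counting the artifact with the code under test.

`generate_corpus` plants a partition: k communities (default 4 × 50
documents), within-community citation probability `p_in = 0.20`, between
`p_out = 0.005`; each document's text mixes a Zipf-like background
vocabulary (500 words, exponent 1.1) with its community's signature term
weighted at 8× the most frequent background word, and every title carries
the corpus filter terms so the corpus passes its own filter.

What passing tests show — and what they do not. Ledger equivalence shows
the audits count exactly what was emitted; planted-partition and
planted-keyword recovery show the detector and the importance statistic
work when the signal is as strong as configured. None of this shows that
real FCDBs follow these distributions: real coverage is not i.i.d.
Bernoulli, real borrowing is correlated across whole table sections, real
citation networks have hubs and degree heterogeneity the planted model
lacks, and real abstracts are not bags of Zipf draws. The generators are
test instruments, not simulations of any national database.

## 7. Numerical and degenerate-input conventions

* `residual = 100 − class_sum` is a single float subtraction — exact in
  the IEEE sense, no rounding applied before comparison.
* Unit conversion multiplies by 1, 1e-3 or 1e-6 exactly once.
* Empty panel → zero coverage matrix over the declared index sets (not an
  error); empty graph → empty partition; fewer than two cross-source
  values, or a zero-dated scope for `fraction_before`, raise scope/domain
  errors rather than returning NaN.
* All stochastic components (generators, community restarts) are seeded;
  CLI stages derive child seeds from one top-level seed via
  `numpy.random.SeedSequence`.

## 8. Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen so the full
battery completes in well under a minute of CPU: exhaustive modularity
comparison on 50 graphs of ≤ 8 nodes (Bell(8) = 4 140 partitions each),
planted-partition recovery on 200-node graphs over 20 seeds, keyword
recovery on 90-document corpora over 20 seeds, conservation on 100 small
random corpora, and ledger equivalence on 10 random panel configurations.
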