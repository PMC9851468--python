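"""Community keyword labels via an n-gram importance statistic.

For a community C of documents, the importance of an n-gram g is

    importance(g) = freq_in(g) - freq_out(g)

where ``freq_in`` is g's count over C's documents divided by the total
n-gram count of C (for the same n), and ``freq_out`` is the analogous
normalized frequency over all documents *outside* C. Terms common to the
whole corpus (e.g. the very keywords the corpus was filtered on) score near
zero; terms over-expressed inside the community score highest and make good
labels.

Normalization is per n (unigram counts normalize against unigram totals,
bigrams against bigrams, ...); the rankings are then merged. Consequence:
for every n, the importances over the union vocabulary sum to zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from ..errors import DomainError
from ..model import Document
from .network import Partition
from .text import tokenize

__all__ = ["KeywordScore", "extract_ngrams", "importance_scores", "top_keywords", "write_scores"]

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KeywordScore:
    """One n-gram with its normalized in/out frequencies and importance."""

    ngram: tuple[str, ...]
    freq_in: float
    freq_out: float

    @property
    def importance(self) -> float:
        return self.freq_in - self.freq_out


def extract_ngrams(
    text: str,
    n_range: tuple[int, int] = (1, 3),
    stopwords: frozenset[str] = frozenset(),
) -> Counter:
    """Count n-grams of the tokenized text for each n in ``n_range``.

    An n-gram containing a stopword is dropped entirely (so stopwords also
    break up longer n-grams: "the palm" yields only the unigram "palm").
    """
    lo, hi = n_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid n_range {n_range}")
    tokens = tokenize(text)
    counts: Counter = Counter()
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            gram = tuple(tokens[i : i + n])
            if any(t in stopwords for t in gram):
                continue
            counts[gram] += 1
    return counts


def _doc_set_frequencies(
    docs: Iterable[Document],
    n_range: tuple[int, int],
    stopwords: frozenset[str],
) -> tuple[Counter, dict[int, int]]:
    """Pooled n-gram counts over a document set plus per-n totals."""
    counts: Counter = Counter()
    for doc in docs:
        counts.update(extract_ngrams(doc.text, n_range, stopwords))
    totals: dict[int, int] = {}
    for gram, c in counts.items():
        totals[len(gram)] = totals.get(len(gram), 0) + c
    return counts, totals


def importance_scores(
    partition: Union[Partition, Mapping[str, str]],
    corpus: Sequence[Document],
    community: str,
    n_range: tuple[int, int] = (1, 3),
    stopwords: frozenset[str] = frozenset(),
) -> list[KeywordScore]:
    """Score every n-gram of the union vocabulary for one community.

    ``partition`` is either an ordered :class:`Partition` (size-rank labels)
    or a plain doc_id -> label mapping; ``community`` is a label such as
    ``"A"``. Documents of the corpus that carry no community (e.g. removed
    as isolated nodes) are ignored. Raises :class:`DomainError` when the
    community or its complement is empty — the statistic is undefined.

    Returns scores sorted by decreasing importance, ties broken
    lexicographically on the n-gram.
    """
    if isinstance(partition, Partition):
        if partition.labels is None:
            raise ValueError("partition must be ordered (call order_communities)")
        label_of = {n: partition.labels[c] for n, c in partition.assignment.items()}
    else:
        label_of = dict(partition)
    docs_in = [d for d in corpus if label_of.get(d.doc_id) == community]
    docs_out = [
        d for d in corpus if d.doc_id in label_of and label_of[d.doc_id] != community
    ]
    if not docs_in:
        raise DomainError(f"community {community!r} is empty")
    if not docs_out:
        raise DomainError("complement is empty; importance undefined")
    counts_in, totals_in = _doc_set_frequencies(docs_in, n_range, stopwords)
    counts_out, totals_out = _doc_set_frequencies(docs_out, n_range, stopwords)
    scores = []
    for gram in set(counts_in) | set(counts_out):
        n = len(gram)
        f_in = counts_in.get(gram, 0) / totals_in[n] if totals_in.get(n) else 0.0
        f_out = counts_out.get(gram, 0) / totals_out[n] if totals_out.get(n) else 0.0
        scores.append(KeywordScore(ngram=gram, freq_in=f_in, freq_out=f_out))
    scores.sort(key=lambda s: (-s.importance, s.ngram))
    return scores


def top_keywords(scores: Sequence[KeywordScore], k: int) -> list[tuple[str, ...]]:
    """First ``k`` n-grams by importance (ties already deterministic).

    When ``k`` exceeds the vocabulary the whole ranking is returned and a
    note is logged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(scores):
        logger.info("k=%d exceeds vocabulary size %d; returning all", k, len(scores))
    return [s.ngram for s in scores[:k]]


def write_scores(
    scores: Sequence[KeywordScore], community: str, path: Union[str, Path]
) -> None:
    """TSV: community_label, rank, ngram, freq_in, freq_out, importance."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("community_label\trank\tngram\tfreq_in\tfreq_out\timportance\n")
        for rank, s in enumerate(scores, start=1):
            fh.write(
                f"{community}\t{rank}\t{' '.join(s.ngram)}\t"
                f"{s.freq_in:.10g}\t{s.freq_out:.10g}\t{s.importance:.10g}\n"
            )
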