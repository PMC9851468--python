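"""Shared tokenization for corpus filtering and n-gram labeling.

Tokenization is deliberately simple and fully specified: lower-case, strip
punctuation, split on non-alphanumeric runs. Keyword matching downstream is
token-exact, so "palmitic" never matches the token "palm" — a substring
match would silently inflate any keyword-filtered corpus.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional, Union

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lower-cased alphanumeric tokens, punctuation removed."""
    return _TOKEN_RE.findall(text.lower())


def load_stopwords(path: Optional[Union[str, Path]] = None) -> frozenset[str]:
    """Load a stopword list (one token per line, ``#`` comments allowed).

    Defaults to the English list shipped with the package.
    """
    if path is None:
        text = resources.files("fcdbaudit.data").joinpath("stopwords_en.txt").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
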