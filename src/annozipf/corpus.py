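"""Word-frequency tables and empirical distribution summaries.

The unit of observation throughout is the word *type*: each distinct word
contributes one observation equal to its total occurrence count in the
dataset.  Tokens are never the observations.  No stemming, stop-word or
number filtering is applied — the distribution is defined over the cleaned
text exactly as produced by :mod:`annozipf.flatfile`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .flatfile import CleanedText

__all__ = ["WordFrequencyTable", "CcdfCurve", "tokenize", "count_words",
           "empirical_ccdf", "tail_sample"]


@dataclass
class WordFrequencyTable:
    """Map word -> occurrence count for one dataset version."""

    version_label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {w: c for w, c in self.counts.items() if c < 1}
        if bad:
            raise ValueError(f"counts must be >= 1; offending words: {sorted(bad)[:5]}")

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())

    def items_sorted(self) -> list[tuple[str, int]]:
        """Descending count, then lexicographic — the reproducible output order."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.items_sorted(), columns=["word", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, version_label: str = "") -> "WordFrequencyTable":
        df = pd.read_csv(path, sep="\t")
        return cls(version_label, dict(zip(df["word"].astype(str), df["count"].astype(int))))


@dataclass
class CcdfCurve:
    """Empirical CCDF over word types: P(a word occurs x or more times)."""

    points: list[tuple[int, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["x", "p"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tokenize(cleaned: Union[CleanedText, str]) -> list[str]:
    """Whitespace split of cleaned text; empty tokens dropped, order kept."""
    text = cleaned.tokens_source if isinstance(cleaned, CleanedText) else cleaned
    return text.split()


def count_words(entries: Iterable[Union[CleanedText, str]], version_label: str = "") -> WordFrequencyTable:
    """Aggregate word counts over all entries of one dataset version."""
    counter: Counter[str] = Counter()
    for cleaned in entries:
        counter.update(tokenize(cleaned))
    return WordFrequencyTable(version_label, dict(counter))


def empirical_ccdf(table: WordFrequencyTable) -> CcdfCurve:
    """For each distinct count x: p(x) = (#word types with count >= x) / n_types.

    The curve is sorted ascending in x; the first point always has p = 1 at
    the minimum observed count (every word occurs at least that often).
    """
    if table.n_types == 0:
        raise ValueError("empty word-frequency table has no CCDF")
    counts = np.sort(np.fromiter(table.counts.values(), dtype=np.int64))
    xs, first_idx = np.unique(counts, return_index=True)
    n = counts.size
    # #types with count >= x equals n minus the index of x's first occurrence
    ps = (n - first_idx) / n
    return CcdfCurve(points=[(int(x), float(p)) for x, p in zip(xs, ps)])


def tail_sample(table: WordFrequencyTable, x_min: int) -> np.ndarray:
    """Per-type occurrence counts >= x_min — the power-law likelihood's data."""
    if x_min < 1:
        raise ValueError("x_min must be >= 1")
    tail = np.sort(np.fromiter((c for c in table.counts.values() if c >= x_min), dtype=np.int64))
    if tail.size == 0:
        raise ValueError(
            f"no word type occurs >= {x_min} times in {table.version_label or 'table'}; "
            "a power-law fit is impossible")
    return tail
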