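"""Gendered lexical contrast via additively smoothed odds ratios.

For a word *w*, with ``Wf(w)`` its token frequency in female-authored
disclosures, ``Wf(~w)`` the frequency of all other female tokens, and the
male quantities defined likewise, the smoothed odds ratio is

    OR(w) = (Wf(w) + a) * (Wm(~w) + a) / ((Wm(w) + a) * (Wf(~w) + a))

with additive smoothing ``a`` (default 1) keeping every ratio finite.
OR > 1 marks a word as more characteristic of the female group; the reverse
contrast swaps the roles of the two groups.  The module also builds
co-occurrence networks over the top-ranked words (edge weight = number of
posts containing both endpoint words) and samples posts per word for
qualitative reading.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .corpus import TweetRecord
from .resources import load_stopwords

FEMALE = "female"
MALE = "male"

#: analysis windows: the year before the pandemic declaration, and the first
#: lockdown wave (March 15 - June 1, 2020), both inclusive
PERIODS: dict[str, tuple[date, date]] = {
    "pre": (date(2019, 3, 15), date(2020, 3, 14)),
    "lockdown": (date(2020, 3, 15), date(2020, 6, 1)),
}

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_NON_ALNUM_RE = re.compile(r"[^0-9a-z\s]", re.UNICODE)


def strip_urls(text: str) -> str:
    return _URL_RE.sub(" ", text)


def preprocess(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """URL removal, special-character stripping (smileys included),
    case-folding, whitespace tokenization, stopword removal.

    Special characters are deleted in place (not turned into spaces), so
    "I'm" becomes the single token "im".
    """
    if stopwords is None:
        stopwords = load_stopwords()
    text = strip_urls(text).casefold()
    text = _NON_ALNUM_RE.sub("", text)
    return [tok for tok in text.split() if tok and tok not in stopwords]


@dataclass
class GenderedWordStats:
    """Per-gender token frequency tables behind the odds-ratio formula."""

    female_counts: Counter = field(default_factory=Counter)
    male_counts: Counter = field(default_factory=Counter)

    @property
    def total_female(self) -> int:
        return sum(self.female_counts.values())

    @property
    def total_male(self) -> int:
        return sum(self.male_counts.values())

    def wf(self, word: str) -> int:
        return self.female_counts.get(word, 0)

    def wm(self, word: str) -> int:
        return self.male_counts.get(word, 0)

    def wf_not(self, word: str) -> int:
        return self.total_female - self.wf(word)

    def wm_not(self, word: str) -> int:
        return self.total_male - self.wm(word)

    def vocabulary(self) -> set[str]:
        return set(self.female_counts) | set(self.male_counts)


@dataclass(frozen=True)
class ContrastResult:
    word: str
    odds_ratio: float
    wf: int
    wm: int
    total_female: int
    total_male: int
    alpha: float
    direction: str  # "female" (female-vs-male) or "male" (reverse)
    period: str | None = None


def slice_period(tweets: Iterable[TweetRecord], period: str) -> list[TweetRecord]:
    start, end = PERIODS[period]
    return [t for t in tweets if start <= t.day <= end]


def word_frequencies(tweets: Iterable[TweetRecord],
                     stopwords: frozenset[str] | None = None) -> GenderedWordStats:
    """Token counts (with multiplicity) per gender over preprocessed text."""
    if stopwords is None:
        stopwords = load_stopwords()
    stats = GenderedWordStats()
    for t in tweets:
        if t.gender == FEMALE:
            stats.female_counts.update(preprocess(t.text, stopwords))
        elif t.gender == MALE:
            stats.male_counts.update(preprocess(t.text, stopwords))
    return stats


def odds_ratio(word: str, stats: GenderedWordStats, alpha: float = 1.0) -> float:
    """Smoothed odds ratio of ``word`` for the female-vs-male contrast."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    num = (stats.wf(word) + alpha) * (stats.wm_not(word) + alpha)
    den = (stats.wm(word) + alpha) * (stats.wf_not(word) + alpha)
    return num / den


def top_k_by_or(stats: GenderedWordStats, k: int = 100,
                direction: str = FEMALE, alpha: float = 1.0,
                min_count: int = 5,
                period: str | None = None) -> list[ContrastResult]:
    """Top-``k`` words by odds ratio for one direction.

    Words with an own-group raw count below ``min_count`` are excluded
    before ranking (without a floor, hapax words with zero opposite-group
    count dominate the list).  Ties break by higher own-group count, then
    lexicographically, so output order is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in (FEMALE, MALE):
        raise ValueError(f"unknown direction {direction!r}")
    results = []
    for word in stats.vocabulary():
        own = stats.wf(word) if direction == FEMALE else stats.wm(word)
        if own < min_count:
            continue
        orr = odds_ratio(word, stats, alpha)
        if direction == MALE:
            orr = 1.0 / orr
        results.append(ContrastResult(
            word=word, odds_ratio=orr, wf=stats.wf(word), wm=stats.wm(word),
            total_female=stats.total_female, total_male=stats.total_male,
            alpha=alpha, direction=direction, period=period))
    results.sort(key=lambda r: (
        -r.odds_ratio, -(r.wf if direction == FEMALE else r.wm), r.word))
    return results[:k]


def overlap_words(top_a: Sequence[ContrastResult],
                  top_b: Sequence[ContrastResult]) -> set[str]:
    """Words recurring in both periods' top lists (exact set intersection)."""
    return {r.word for r in top_a} & {r.word for r in top_b}


def cooccurrence_network(tweets: Iterable[TweetRecord],
                         word_list: Sequence[ContrastResult] | Sequence[str],
                         stopwords: frozenset[str] | None = None,
                         period: str | None = None,
                         direction: str | None = None) -> nx.Graph:
    """Graph over the listed words; an edge's weight is the number of posts
    whose token *set* contains both endpoints (within-post multiplicity is
    ignored).  Nodes carry the odds ratio when built from contrast results."""
    if stopwords is None:
        stopwords = load_stopwords()
    if not word_list:
        raise ValueError("word_list must be non-empty")
    or_by_word: dict[str, float] = {}
    words: list[str] = []
    for item in word_list:
        if isinstance(item, ContrastResult):
            words.append(item.word)
            or_by_word[item.word] = item.odds_ratio
        else:
            words.append(str(item))
    graph = nx.Graph(period=period or "", direction=direction or "")
    for w in words:
        graph.add_node(w, word=w, odds_ratio=float(or_by_word.get(w, 1.0)))
    listed = set(words)
    for t in tweets:
        present = sorted(set(preprocess(t.text, stopwords)) & listed)
        for a, b in combinations(present, 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    return graph


def export_network(graph: nx.Graph, path: str | Path,
                   scale_by_or: bool = True, fmt: str | None = None,
                   base_size: float = 10.0) -> Path:
    """Write GraphML (default) or GEXF with node size proportional to OR.

    Force-directed layout is left to downstream tools; only attributes are
    exported.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gexf" if path.suffix.lower() == ".gexf" else "graphml"
    out = nx.Graph(**graph.graph)
    for node, attrs in graph.nodes(data=True):
        a = dict(attrs)
        if scale_by_or:
            a["size"] = base_size * float(a.get("odds_ratio", 1.0))
        out.add_node(node, **a)
    out.add_edges_from(graph.edges(data=True))
    if fmt == "gexf":
        nx.write_gexf(out, path)
    else:
        nx.write_graphml(out, path)
    return path


def sample_tweets_for_word(tweets: Sequence[TweetRecord], word: str,
                           n: int = 50, seed: int = 0,
                           gender: str | None = None,
                           stopwords: frozenset[str] | None = None
                           ) -> list[TweetRecord]:
    """Up to ``n`` posts containing ``word``, uniformly at random without
    replacement; all of them when fewer than ``n`` match."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if stopwords is None:
        stopwords = load_stopwords()
    matching = [t for t in tweets
                if (gender is None or t.gender == gender)
                and word in set(preprocess(t.text, stopwords))]
    if len(matching) <= n:
        return matching
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(matching), size=n, replace=False)
    return [matching[i] for i in sorted(idx)]
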