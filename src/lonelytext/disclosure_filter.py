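"""Reduce a keyword-matched stream to loneliness self-disclosures.

Stages, in the fixed order used throughout the pipeline:

1. keyword prefilter — emulates the stream collection: case-folded token
   match on the collection keywords ("lonely", "loneliness"; "alone" is
   deliberately not a keyword) plus an English language-tag restriction;
2. rule filter — URL posts, retweets, known lyric/art phrases, and posts
   that are empty once special characters and URLs are stripped;
3. a re-trainable linear-margin (SVM) classifier over token counts,
   evaluated by pooled out-of-fold cross-validation.

The annotation-agreement statistic (Cohen's kappa) for double-coded labels
lives here as well.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .corpus import TweetRecord
from .lexical_contrast import preprocess, strip_urls, _NON_ALNUM_RE
from .resources import load_default_lyrics

DEFAULT_KEYWORDS = frozenset({"lonely", "loneliness"})


class FilterReason(str, Enum):
    KEPT = "kept"
    HAS_URL = "has_url"
    IS_RETWEET = "is_retweet"
    EMPTY_AFTER_CLEANING = "empty_after_cleaning"
    LYRIC_MATCH = "lyric_match"
    CLASSIFIER_NEGATIVE = "classifier_negative"
    WRONG_LANGUAGE = "wrong_language"


@dataclass(frozen=True)
class FilterDecision:
    tweet_id: int
    kept: bool
    reason: FilterReason

    def __post_init__(self):
        if self.kept != (self.reason == FilterReason.KEPT):
            raise ValueError("kept flag must match reason")


def _keyword_tokens(text: str) -> set[str]:
    cleaned = _NON_ALNUM_RE.sub(" ", text.casefold())
    return set(cleaned.split())


def keyword_prefilter(tweets: Iterable[TweetRecord],
                      keywords: frozenset[str] | set[str] = DEFAULT_KEYWORDS
                      ) -> list[TweetRecord]:
    """Posts whose case-folded token set hits a collection keyword, with the
    language tag restricted to English."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    keywords = {k.casefold() for k in keywords}
    return [t for t in tweets
            if t.lang == "en" and _keyword_tokens(t.text) & keywords]


def cleaned_residue(text: str) -> str:
    """Text after URL removal and special-character stripping, trimmed."""
    return _NON_ALNUM_RE.sub("", strip_urls(text).casefold()).strip()


def rule_filter(tweet: TweetRecord,
                lyric_phrases: Sequence[str] | None = None) -> FilterDecision:
    """First matching exclusion in the fixed order
    url -> retweet -> lyric -> empty-after-cleaning."""
    if lyric_phrases is None:
        lyric_phrases = load_default_lyrics()
    if tweet.urls:
        reason = FilterReason.HAS_URL
    elif tweet.retweeted:
        reason = FilterReason.IS_RETWEET
    elif any(p.casefold() in tweet.text.casefold() for p in lyric_phrases):
        reason = FilterReason.LYRIC_MATCH
    elif not cleaned_residue(tweet.text):
        reason = FilterReason.EMPTY_AFTER_CLEANING
    else:
        reason = FilterReason.KEPT
    return FilterDecision(tweet_id=tweet.id, kept=reason == FilterReason.KEPT,
                          reason=reason)


def apply_rule_filter(tweets: Iterable[TweetRecord],
                      lyric_phrases: Sequence[str] | None = None
                      ) -> tuple[list[TweetRecord], list[FilterDecision]]:
    kept, decisions = [], []
    for t in tweets:
        d = rule_filter(t, lyric_phrases)
        decisions.append(d)
        if d.kept:
            kept.append(t)
    return kept, decisions


@dataclass
class DisclosureClassifier:
    """Fitted linear-margin model over token-count features.

    ``fold_assignments`` records which cross-validation fold each training
    example was evaluated in; the harness never scores an example with a
    model that saw it during fitting.
    """

    vectorizer: CountVectorizer
    model: LinearSVC
    n_folds: int
    seed: int
    fold_assignments: np.ndarray = field(default=None, repr=False)

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return self.model.predict(self.vectorizer.transform(texts))

    def predict_tweets(self, tweets: Sequence[TweetRecord]) -> np.ndarray:
        return self.predict([t.text for t in tweets])


def _make_pipeline_parts(seed: int):
    vectorizer = CountVectorizer(analyzer=preprocess, min_df=1)
    model = LinearSVC(C=1.0, random_state=seed)
    return vectorizer, model


def train_disclosure_classifier(texts: Sequence[str], labels: Sequence[int],
                                n_folds: int = 5, seed: int = 0
                                ) -> tuple[DisclosureClassifier, float, float]:
    """Fit the disclosure classifier; report pooled out-of-fold precision
    and recall, then refit on all data.

    Raises ``ValueError`` unless both classes have at least two examples
    and ``n_folds >= 2``.
    """
    labels = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    class_counts = Counter(labels.tolist())
    if len(class_counts) < 2 or min(class_counts.values()) < 2:
        raise ValueError("need at least two examples of each class")
    n_folds = min(n_folds, min(class_counts.values()))

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    texts = list(texts)
    oof = np.full(len(texts), -1, dtype=int)
    fold_of = np.full(len(texts), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(texts, labels)):
        vec, mod = _make_pipeline_parts(seed)
        X_train = vec.fit_transform([texts[i] for i in train_idx])
        mod.fit(X_train, labels[train_idx])
        X_test = vec.transform([texts[i] for i in test_idx])
        oof[test_idx] = mod.predict(X_test)
        fold_of[test_idx] = fold

    tp = int(np.sum((oof == 1) & (labels == 1)))
    fp = int(np.sum((oof == 1) & (labels == 0)))
    fn = int(np.sum((oof == 0) & (labels == 1)))
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    vec, mod = _make_pipeline_parts(seed)
    X_all = vec.fit_transform(texts)
    mod.fit(X_all, labels)
    clf = DisclosureClassifier(vectorizer=vec, model=mod, n_folds=n_folds,
                               seed=seed, fold_assignments=fold_of)
    return clf, precision, recall


def apply_classifier(tweets: Sequence[TweetRecord],
                     classifier: DisclosureClassifier
                     ) -> tuple[list[TweetRecord], list[FilterDecision]]:
    if not tweets:
        return [], []
    preds = classifier.predict_tweets(tweets)
    kept, decisions = [], []
    for t, p in zip(tweets, preds):
        if p == 1:
            kept.append(t)
            decisions.append(FilterDecision(t.id, True, FilterReason.KEPT))
        else:
            decisions.append(
                FilterDecision(t.id, False, FilterReason.CLASSIFIER_NEGATIVE))
    return kept, decisions


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` is the sum over categories of the product of the two
    annotators' marginal proportions.  Returns ``nan`` when ``p_e == 1``
    (both annotators constant on the same category), where kappa is
    undefined.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}")
    n = len(labels_a)
    if n == 0:
        raise ValueError("need at least one label pair")
    p_o = sum(1 for a, b in zip(labels_a, labels_b) if a == b) / n
    cats = set(labels_a) | set(labels_b)
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in cats)
    if math.isclose(p_e, 1.0):
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)
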