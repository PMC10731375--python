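"""Reduce the keyword stream to loneliness self-disclosures.

Applies the language/keyword prefilter, the rule exclusions (URLs,
retweets, lyric phrases, empty-after-cleaning) and the cross-validated SVM
disclosure classifier trained on the generated labels.  Reports how many
posts each stage removed.
"""

import json
from collections import Counter
from pathlib import Path

from lonelytext.corpus import read_tweets, write_tweets
from lonelytext.disclosure_filter import (apply_classifier, apply_rule_filter,
                                          keyword_prefilter,
                                          train_disclosure_classifier)
from lonelytext.synthetic_corpus import read_ground_truth

ROOT = Path(__file__).resolve().parents[1]
SEED = 20200315


def main() -> None:
    corpus_dir = ROOT / "scratch" / "corpus"
    tweets = read_tweets(corpus_dir / "tweets.jsonl")
    truth = read_ground_truth(corpus_dir / "ground_truth.jsonl")

    prefiltered = keyword_prefilter(tweets)
    kept_rules, decisions = apply_rule_filter(prefiltered)
    reason_counts = Counter(d.reason.value for d in decisions if not d.kept)

    labels = [int(truth.tweet_is_disclosure[t.id]) for t in kept_rules]
    clf, precision, recall = train_disclosure_classifier(
        [t.text for t in kept_rules], labels, n_folds=5, seed=SEED)
    kept, clf_decisions = apply_classifier(kept_rules, clf)
    reason_counts["classifier_negative"] = sum(
        1 for d in clf_decisions if not d.kept)

    out_dir = ROOT / "scratch" / "pipeline"
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tweets(kept, out_dir / "kept.jsonl")

    report = {
        "n_input": len(tweets),
        "n_after_keyword_and_language": len(prefiltered),
        "n_kept": len(kept),
        "removed_by_reason": dict(sorted(reason_counts.items())),
        "classifier_cv_precision": precision,
        "classifier_cv_recall": recall,
        "cv_folds": clf.n_folds,
    }
    with open(ROOT / "results" / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"kept {len(kept)}/{len(tweets)} posts as self-disclosures")
    print(f"classifier CV precision={precision:.3f} recall={recall:.3f}")
    print("removals:", dict(sorted(reason_counts.items())))


if __name__ == "__main__":
    main()
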