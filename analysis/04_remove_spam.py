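"""Screen out spam/disingenuous accounts by posting rate.

Flags accounts posting 16+ times per day over their lifetime (profile
status count over account age) or whose cumulative count decreases within
the dataset, and drops all their posts.  Compares the flagged set against
the generator's ground truth.
"""

import json
from pathlib import Path

from lonelytext.activity_filter import apply_activity_filter
from lonelytext.corpus import read_tweets, write_tweets
from lonelytext.synthetic_corpus import read_ground_truth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pipeline = ROOT / "scratch" / "pipeline"
    tweets = read_tweets(pipeline / "gendered.jsonl")
    truth = read_ground_truth(ROOT / "scratch" / "corpus" / "ground_truth.jsonl")

    clean, report = apply_activity_filter(tweets)
    write_tweets(clean, pipeline / "clean.jsonl")

    removed = set(report["flagged_users"])
    present = {t.user.id for t in tweets}
    spam_present = truth.spam_user_ids & present
    genuine_present = present - truth.spam_user_ids
    summary = {
        "n_users_flagged": report["n_users_flagged"],
        "n_tweets_removed": report["n_tweets_removed"],
        "removed_by_reason": report["removed_by_reason"],
        "sensitivity": len(removed & spam_present) / len(spam_present)
        if spam_present else None,
        "specificity": len(genuine_present - removed) / len(genuine_present),
    }
    with open(ROOT / "results" / "spam_report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"flagged {report['n_users_flagged']} accounts, removed "
          f"{report['n_tweets_removed']} posts "
          f"(sensitivity={summary['sensitivity']}, "
          f"specificity={summary['specificity']})")


if __name__ == "__main__":
    main()
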