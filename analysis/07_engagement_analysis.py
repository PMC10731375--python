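"""Response to disclosures: likes, retweets, replies and quotes by gender.

Summarizes the four response metrics per gender, compares their
distributions with two-sided Mann-Whitney tests, and reports the share of
disclosures that received no reply at all.
"""

import json
from pathlib import Path

from lonelytext.corpus import read_tweets
from lonelytext.engagement_stats import engagement_summary, zero_reply_fraction

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tweets = read_tweets(ROOT / "scratch" / "pipeline" / "clean.jsonl")
    summary = engagement_summary(tweets)
    report = summary.to_report()
    report["zero_reply_fraction"] = zero_reply_fraction(tweets)
    with open(ROOT / "results" / "engagement.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for metric in ("like_count", "reply_count"):
        f = summary.per_gender["female"][metric]
        m = summary.per_gender["male"][metric]
        print(f"{metric}: female median {f.median:g} (mean {f.mean:.2f}), "
              f"male median {m.median:g} (mean {m.mean:.2f}), "
              f"MW p={summary.p_values[metric]:.3g}")
    print(f"disclosures with zero replies: "
          f"{report['zero_reply_fraction']:.1%}")


if __name__ == "__main__":
    main()
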