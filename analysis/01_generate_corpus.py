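"""Generate the study corpus.

Builds a synthetic two-gender collection straddling the lockdown date,
with contaminants, spam accounts and ambiguous names active, and stores it
(with ground truth) under scratch/ for the downstream steps.  A small
summary table goes to results/.
"""

import json
from pathlib import Path

from lonelytext.corpus import write_corpus
from lonelytext.synthetic_corpus import (GeneratorConfig, generate_corpus,
                                         write_ground_truth)

ROOT = Path(__file__).resolve().parents[1]

CONFIG = GeneratorConfig(
    n_users_per_gender=800, base_daily_rate=50.0, lockdown_multiplier=1.8,
    study_start="2020-02-01", lockdown_date="2020-03-15",
    study_end="2020-04-26", spam_fraction=0.08,
    outage_dates=("2020-02-20", "2020-02-21", "2020-02-22"),
    seed=20200315)


def main() -> None:
    corpus_dir = ROOT / "scratch" / "corpus"
    tweets, users, truth = generate_corpus(CONFIG)
    write_corpus(tweets, users, corpus_dir)
    write_ground_truth(truth, corpus_dir / "ground_truth.jsonl")

    n_disc = sum(truth.tweet_is_disclosure.values())
    summary = {
        "n_tweets": len(tweets),
        "n_users": len(users),
        "n_true_disclosures": n_disc,
        "n_spam_users": len(truth.spam_user_ids),
        "study_days": (CONFIG.study_end - CONFIG.study_start).days + 1,
        "outage_days": [d.isoformat() for d in CONFIG.outage_dates],
        "pre_intensity_per_gender": truth.pre_intensity,
        "post_intensity_per_gender": truth.post_intensity,
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "corpus_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"corpus: {len(tweets)} tweets, {len(users)} users "
          f"({len(truth.spam_user_ids)} spam), {n_disc} true disclosures")
    print(f"written to {corpus_dir}")


if __name__ == "__main__":
    main()
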