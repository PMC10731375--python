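"""Assign gender from profile names and drop unmatched users.

Uses the packaged name dictionary (baby-name registry schema); users whose
first name token is unattested or attested for both genders are discarded,
mirroring the strict-ambiguity rule.
"""

import json
from pathlib import Path

from lonelytext.corpus import read_tweets, write_tweets
from lonelytext.gender_inference import annotate_genders, default_name_dictionary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    pipeline = ROOT / "scratch" / "pipeline"
    tweets = read_tweets(pipeline / "kept.jsonl")
    annotated, counts = annotate_genders(tweets, default_name_dictionary())
    write_tweets(annotated, pipeline / "gendered.jsonl")
    with open(ROOT / "results" / "gender_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    total = sum(counts.values())
    print(f"female={counts['female']} male={counts['male']} "
          f"dropped_unknown={counts['unknown']} "
          f"({counts['unknown'] / total:.1%} of disclosures)")


if __name__ == "__main__":
    main()
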