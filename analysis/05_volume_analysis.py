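"""Daily posting volume by gender and the lockdown step.

Builds per-gender unique-user series, repairs the simulated collection
outage by linear interpolation, compares the weeks around the lockdown
date with a one-sided Welch t-test, and reports gender co-movement
(Pearson) and posts-per-account (Mann-Whitney).
"""

import json
from pathlib import Path

from lonelytext.corpus import read_tweets
from lonelytext.volume_timeseries import (daily_unique_users, interpolate_gaps,
                                          posts_per_account,
                                          series_correlation, series_to_frame,
                                          window_compare)

import importlib.util as _ilu

ROOT = Path(__file__).resolve().parents[1]
_spec = _ilu.spec_from_file_location(
    "gen_step", ROOT / "analysis" / "01_generate_corpus.py")
_gen = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_gen)
CONFIG = _gen.CONFIG


def main() -> None:
    tweets = read_tweets(ROOT / "scratch" / "pipeline" / "clean.jsonl")
    start, end = CONFIG.study_start, CONFIG.study_end
    series = {g: interpolate_gaps(daily_unique_users(tweets, g, start, end),
                                  CONFIG.outage_dates)
              for g in ("female", "male")}
    frame = series_to_frame(series["female"], series["male"])
    frame.to_csv(ROOT / "results" / "daily_volume.csv", index=False)

    stats = {"pearson_r": series_correlation(series["female"],
                                             series["male"])}
    for g in ("female", "male"):
        wc = window_compare(series[g], CONFIG.lockdown_date)
        stats[g] = {"mean_week_before": wc.mean_pre, "sd_before": wc.sd_pre,
                    "mean_week_after": wc.mean_post, "sd_after": wc.sd_post,
                    "p_one_sided": wc.p_one_sided}
        print(f"{g}: {wc.mean_pre:.1f} (sd {wc.sd_pre:.1f}) -> "
              f"{wc.mean_post:.1f} (sd {wc.sd_post:.1f}) unique users/day, "
              f"one-sided Welch p={wc.p_one_sided:.2e}")
    ppa = posts_per_account(tweets)
    stats["posts_per_account"] = {
        "female_mean": ppa.mean_female, "female_sd": ppa.sd_female,
        "male_mean": ppa.mean_male, "male_sd": ppa.sd_male,
        "mann_whitney_p": ppa.p_two_sided}
    with open(ROOT / "results" / "volume_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"gender series Pearson r = {stats['pearson_r']:.3f}")
    print(f"posts/account: female {ppa.mean_female:.2f} "
          f"vs male {ppa.mean_male:.2f} (MW p={ppa.p_two_sided:.3g})")


if __name__ == "__main__":
    main()
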