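"""Filter the simulated streams and compute event-aligned rate series.

Reads the raw streams written by 01_simulate.py, applies the standard
filters (candidate terms + meme term, drop URLs and retweets), bins at one
second, and writes per-debate tidy rate tables to scratch/ plus a channel
summary (totals, per-second mean/SD, share of attention per candidate) to
results/rate_summary.csv.

Run:  python analysis/02_rates.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from entrainkit import io as ekio
from entrainkit.synth import truth_from_report
from entrainkit.pipeline import default_filter_spec
from entrainkit.timeline import align_and_bin, filter_messages, mention_proportion

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for debate in (1, 2, 3):
        indir = ROOT / "scratch" / "synthetic" / f"debate{debate}"
        if not indir.exists():
            raise SystemExit(f"{indir} missing - run analysis/01_simulate.py first")
        annotation = ekio.read_annotation(indir / "annotation.json")
        messages = ekio.read_messages(indir / "messages.jsonl")
        import json

        truth = truth_from_report(json.loads((indir / "truth.json").read_text()))
        spec = default_filter_spec(annotation, truth)
        by_term = filter_messages(messages, spec)
        series = align_and_bin(by_term, annotation, 1.0)
        ekio.write_rates(series, indir / "rates.csv")

        cand_a, cand_b = [s for s in annotation.speakers if s != "moderator"][:2]
        prop = mention_proportion(series, cand_a, cand_b, smooth_bins=30)
        for channel, counts in sorted(series.channels.items()):
            rows.append(
                {
                    "debate": debate,
                    "channel": channel,
                    "total": int(counts.sum()),
                    "mean_per_s": round(float(counts.mean()), 3),
                    "sd_per_s": round(float(counts.std()), 3),
                }
            )
        print(
            f"debate {debate}: kept {int(series.channels['total'].sum())} messages; "
            f"mean share of '{cand_a}' mentions "
            f"{np.nanmean(prop):.3f} (smoothed 30 s)"
        )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "rate_summary.csv", index=False)
    print(f"wrote {results / 'rate_summary.csv'}")


if __name__ == "__main__":
    main()
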