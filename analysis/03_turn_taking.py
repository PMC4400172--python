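"""Timescale 1: do turn-taking and interruptions entrain the message rate?

For each simulated debate and each candidate channel, fits the speaker
mixed model (floor-holding x speaking time, random structure by turn) and,
per debate, the interruption model on the total rate.  The generator's
truth is speaker_boost = interruption_boost = 1.5 with within-turn slopes
of +-0.01/s, so the expected pattern is a positive speaker effect, a
positive interruption effect, and a positive speaker x speaking-time
interaction.  Writes results/turn_taking_models.csv.

Run:  python analysis/03_turn_taking.py [--base-seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from entrainkit.interaction import (
    build_turn_design,
    fit_interruption_model,
    fit_speaker_model,
)
from entrainkit.pipeline import simulate_event

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--base-seed", type=int, default=1)
    args = ap.parse_args()

    rows = []
    for debate in (1, 2, 3):
        ev = simulate_event(seed=args.base_seed + debate)
        principals = [s for s in ev.annotation.speakers if s != "moderator"][:2]
        for cand in principals:
            design = build_turn_design(ev.annotation, ev.series, cand)
            res = fit_speaker_model(design)
            for name, beta, t, p in res.coefficients:
                if name == "Intercept":
                    continue
                rows.append(
                    {
                        "debate": debate,
                        "model": "speaker",
                        "channel": cand,
                        "term": name,
                        "beta": round(beta, 3),
                        "t": round(t, 2),
                        "p": f"{p:.2g}",
                        "r2_marginal": round(res.r2_marginal, 3),
                        "r2_conditional": round(res.r2_conditional, 3),
                    }
                )
            beta, t, _ = res.coef("speaker")
            print(
                f"debate {debate} '{cand}': speaker beta {beta:+.2f} (t {t:.1f}), "
                f"R2m {res.r2_marginal:.2f} R2c {res.r2_conditional:.2f}"
            )

        design = build_turn_design(ev.annotation, ev.series, principals[0])
        res = fit_interruption_model(design)
        for name, beta, t, p in res.coefficients:
            if name == "Intercept":
                continue
            rows.append(
                {
                    "debate": debate,
                    "model": "interruption",
                    "channel": "total",
                    "term": name,
                    "beta": round(beta, 3),
                    "t": round(t, 2),
                    "p": f"{p:.2g}",
                    "r2_marginal": round(res.r2_marginal, 3),
                    "r2_conditional": round(res.r2_conditional, 3),
                }
            )
        beta, t, _ = res.coef("interruption")
        print(f"debate {debate} total: interruption beta {beta:+.2f} (t {t:.1f})")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "turn_taking_models.csv", index=False)
    print(f"wrote {results / 'turn_taking_models.csv'}")


if __name__ == "__main__":
    main()
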