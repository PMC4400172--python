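"""Timescale 3: whole-event rise and fall of attention.

Fits the standardized quadratic trend to each debate's total rate and runs
the second-half decay test (quadratic term alone on the second half).  The
generator applies (0.3, -0.5) on normalised time to the log rate, so the
expected pattern is a positive linear beta, a negative quadratic beta, and
a significantly negative second-half decay.  Writes
results/longterm_trend.csv.

Run:  python analysis/05_longterm.py [--base-seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from entrainkit.pipeline import simulate_event
from entrainkit.trend import fit_quadratic

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--base-seed", type=int, default=1)
    args = ap.parse_args()

    rows = []
    for debate in (1, 2, 3):
        ev = simulate_event(seed=args.base_seed + debate)
        res = fit_quadratic(ev.series, "total")
        beta2, t2, p2 = res.second_half
        rows.append(
            {
                "debate": debate,
                "beta_linear": round(res.beta_linear, 3),
                "t_linear": round(res.t_linear, 1),
                "beta_quadratic": round(res.beta_quadratic, 3),
                "t_quadratic": round(res.t_quadratic, 1),
                "r2": round(res.r2, 3),
                "second_half_beta": round(beta2, 3),
                "second_half_t": round(t2, 1),
                "second_half_p": f"{p2:.2g}",
            }
        )
        print(
            f"debate {debate}: linear {res.beta_linear:+.2f} (t {res.t_linear:.0f}), "
            f"quadratic {res.beta_quadratic:+.2f} (t {res.t_quadratic:.0f}), "
            f"R2 {res.r2:.3f}; second-half decay beta {beta2:+.2f} (p {p2:.1g})"
        )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "longterm_trend.csv", index=False)
    print(f"wrote {results / 'longterm_trend.csv'}")


if __name__ == "__main__":
    main()
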