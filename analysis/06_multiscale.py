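"""All timescales at once: combined regression, unique variance, transfer.

Per debate, assembles the per-second design (quadratic time, speaker
duration, interruption, fitted salient kernel, pairwise interactions),
fits the combined OLS model, and decomposes each block's unique variance
by entering it last.  Then refits debate 1 without the salient block (a
post-hoc quantity that does not generalise) and transfers its coefficients
to debates 2 and 3, reporting the Pearson r between predicted and observed
rates.  Writes results/multiscale_models.csv and results/transfer.csv.

Run:  python analysis/06_multiscale.py [--base-seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from entrainkit.meme import fit_meme
from entrainkit.multiscale import build_full_design, fit_multiscale, transfer_predict
from entrainkit.pipeline import simulate_event
from entrainkit.timeline import event_locked_window

ROOT = Path(__file__).resolve().parents[1]
WINDOW_S = 600.0


def fitted_kernels(ev):
    fits = []
    for kernel in ev.truth.meme_kernels:
        win = event_locked_window(
            ev.series, onset_s=kernel.onset_s, pre_s=0.0, post_s=WINDOW_S
        )
        fit = fit_meme(win, kernel.match_term, window_s=WINDOW_S)
        fits.append((kernel.onset_s, fit.params))
    return fits


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--base-seed", type=int, default=1)
    args = ap.parse_args()

    events = {d: simulate_event(seed=args.base_seed + d) for d in (1, 2, 3)}

    rows = []
    for debate, ev in events.items():
        design = build_full_design(ev.annotation, ev.series, fitted_kernels(ev))
        res = fit_multiscale(design)
        rows.append(
            {
                "debate": debate,
                "r2": round(res.r2, 3),
                **{
                    f"unique_{block}": round(delta, 4)
                    for block, delta in sorted(res.unique_r2.items())
                },
            }
        )
        uniq = ", ".join(f"{b} {d:.3f}" for b, d in sorted(res.unique_r2.items()))
        print(f"debate {debate}: R2 {res.r2:.3f}; unique variance {uniq}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "multiscale_models.csv", index=False)

    # transfer: debate 1 model (no salient block) applied to debates 2 and 3
    src = events[1]
    src_design = build_full_design(src.annotation, src.series, None)
    src_fit = fit_multiscale(src_design, compute_unique=False)
    transfer_rows = []
    for debate in (2, 3):
        tgt = events[debate]
        tgt_design = build_full_design(tgt.annotation, tgt.series, None)
        r = transfer_predict(src_fit, tgt_design)
        transfer_rows.append(
            {"source": 1, "target": debate, "r": round(r, 3), "n_seconds": len(tgt_design.y)}
        )
        print(f"transfer debate 1 -> {debate}: r = {r:.3f}")
    pd.DataFrame(transfer_rows).to_csv(results / "transfer.csv", index=False)
    print(f"wrote {results / 'multiscale_models.csv'} and {results / 'transfer.csv'}")


if __name__ == "__main__":
    main()
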