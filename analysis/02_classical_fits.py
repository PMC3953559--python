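#!/usr/bin/env python
"""Fit all six height-diameter forms to campaign 1 by nonlinear least squares.

Produces the classical half of the model-comparison table: parameter
estimates with Wald 95% confidence intervals and RMSE per form, ranked
by RMSE.  Expects the CSVs written by 01_simulate_campaigns.py (falls
back to regenerating them).
"""

import argparse
from pathlib import Path

import hdbayes as hb
from hdbayes.io import read_dataset

def load_campaign1(results_dir: Path, seed: int):
    path = results_dir / "campaign1_trees.csv"
    if path.exists():
        return read_dataset(path)
    return hb.generate_dataset(hb.data1_like(seed=seed))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = load_campaign1(out, args.seed)
    fits = [hb.fit_nls(ds, m) for m in hb.MODEL_IDS]
    report = hb.ComparisonReport(fits=fits)
    table = report.table().round(4)
    table.to_csv(out / "classical_fits.csv", index=False)
    print(table.to_string(index=False))
    ranking = report.ranking("rmse")
    print("\nranking by RMSE:", " < ".join(ranking))
    print(f"best form: {ranking[0]}")


if __name__ == "__main__":
    main()
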