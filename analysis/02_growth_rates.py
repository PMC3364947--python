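#!/usr/bin/env python
"""Fit growth rates for both strains in each condition and compare them.

Reads the long-format growth curves from 01, fits the logistic growth model
per well, pools posterior draws across replicate wells, and reports rates with
95% CIs plus the mutant/WT rate ratio per condition (two conditions are called
significantly different when their ratio CIs do not overlap).
Writes results/growth_rates.tsv and results/growth_ratios.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rholandscape.growth import (
    fit_condition_table,
    fit_growth_model,
    growth_rate_ratio,
    lag_and_saturation,
    read_growth_long,
    sample_posterior,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    curves = read_growth_long(ROOT / "data" / "growth_curves.tsv")
    table = fit_condition_table(curves, n_posterior=4000, seed=2)
    table.to_csv(ROOT / "growth_rates.tsv", sep="\t", index=False)
    print("growth rates (doublings/hour):")
    print(table.to_string(index=False))

    rows = []
    for condition in sorted({c for _, c in curves}):
        pooled = {}
        for strain in ("WT", "rhostar"):
            draws = []
            for i, curve in enumerate(curves[(strain, condition)]):
                fit = sample_posterior(fit_growth_model(curve), n=1000, seed=100 + i)
                draws.append(fit.gamma_samples)
            pooled[strain] = np.concatenate(draws)
        ratio = growth_rate_ratio(pooled["rhostar"], pooled["WT"])
        rows.append(
            {
                "condition": condition,
                "gamma_ratio": round(ratio.gamma_ratio, 4),
                "ci_low": round(ratio.ci_low, 4),
                "ci_high": round(ratio.ci_high, 4),
            }
        )
    ratios = pd.DataFrame(rows)
    ratios.to_csv(ROOT / "growth_ratios.tsv", sep="\t", index=False)
    print("\nmutant/WT rate ratios:")
    print(ratios.to_string(index=False))

    curve = curves[("WT", "glucose")][0]
    lag, tsat = lag_and_saturation(curve)
    print(f"\nexample WT/glucose well: lag {lag:.2f} h, time to saturation {tsat:.2f} h")


if __name__ == "__main__":
    main()
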