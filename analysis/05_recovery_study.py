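#!/usr/bin/env python
"""Monte-Carlo study of K_D estimator accuracy and CI calibration.

Regenerates the fixture at default noise over 100 seeds, refits each, and
tabulates the relative K_D error and whether the covariance-based 95% CI
covers the generating value. Writes results/recovery.csv and prints the
summary statistics; see docs/methods.md for why the precision at these
titration conditions is limited (~14% Fisher standard error).
"""

import csv
from pathlib import Path

import numpy as np

from csptitr import build_csp_table, global_fit, make_fixture_hfyn

ROOT = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 100


def main():
    rows = []
    for seed in range(N_SEEDS):
        series, truth = make_fixture_hfyn(seed=seed)
        csp = build_csp_table(series)
        fit = global_fit(csp, series, protein_conc=truth["protein_conc"])
        lo, hi = fit.ci95["K_D"]
        rows.append({
            "seed": seed,
            "K_D": round(fit.K_D, 4),
            "rel_error": round(fit.K_D / truth["K_D"] - 1, 5),
            "ci_lo": round(lo, 4),
            "ci_hi": round(hi, 4),
            "covered": int(lo <= truth["K_D"] <= hi),
            "n_significant": int(csp.data["significant"].sum()),
        })
    out = ROOT / "recovery.csv"
    out.parent.mkdir(exist_ok=True)
    with open(out, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=rows[0].keys())
        writer.writeheader()
        writer.writerows(rows)

    err = np.array([r["rel_error"] for r in rows])
    cov = np.array([r["covered"] for r in rows])
    print(f"{N_SEEDS} seeds at default noise, K_D truth 48 uM:")
    print(f"  median |relative error| = {np.median(np.abs(err)):.3f}")
    print(f"  mean relative error     = {err.mean():+.3f} (near-unbiased)")
    print(f"  error sd                = {err.std():.3f}")
    print(f"  95% CI coverage         = {cov.mean():.2f}")
    print(f"  significance count always 12: {all(r['n_significant'] == 12 for r in rows)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
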