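#!/usr/bin/env python
"""Generate the synthetic hFynSH3-mimic titration series used by the analysis.

Emulates the automated microfluidic experiment: 11 HSQC peak lists (1
protein-only + 10 displacement-mixing injections of ~2 μL into a 10 μL
circuit), TSP internal-standard intensities, K_D = 48 μM at [P] = 1000 μM,
default observation noise. Writes the series, manifest, and ground-truth
sidecar under results/series/.
"""

import json
from pathlib import Path

from csptitr import make_fixture_hfyn, write_fixture

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "series"


def main():
    series, truth = make_fixture_hfyn(seed=SEED)
    manifest = write_fixture(series, truth, OUT)
    print(f"wrote {series.n_steps}-step series to {OUT}")
    print(f"manifest: {manifest}")
    print(f"ground truth: K_D = {truth['K_D']} uM, beta_D = {truth['beta_D']}, "
          f"alpha_max = {truth['alpha_max']}")
    print(f"alpha per step: {[round(a, 3) for a in truth['alpha']]}")
    print(f"{truth['n_labels']} amide labels, "
          f"{len(truth['perturbed_labels'])} perturbed (ground truth): "
          f"{truth['perturbed_labels']}")


if __name__ == "__main__":
    main()
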