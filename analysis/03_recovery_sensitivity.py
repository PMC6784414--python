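#!/usr/bin/env python
"""Parameter-recovery and landmark-noise sensitivity study.

Fifty random synthetic limbs are generated and measured noiselessly
(every metric should come back within 2% of its analytic truth; in
practice only the voxel-counted QCA deviates measurably), then the same
fifty limbs are re-generated with 1 mm isotropic landmark noise and the
moment-arm recovery error is tabulated (bias, SD, mean and max absolute
relative error).  Writes results/recovery.csv and
results/moment_arm_sensitivity.csv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from stiflemetrics import measure_limb
from stiflemetrics.anatomy import build_frame
from stiflemetrics.static_metrics import (
    METRIC_FIELDS,
    extensor_line_of_action,
    moment_arm,
    transepicondylar_axis,
)
from stiflemetrics.synthetic import generate_limb, random_spec

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026
N_COHORT = 50
SIGMA_MM = 1.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(SEED).generate_state(N_COHORT) % (2**31 - 1)

    rows = []
    for s in seeds:
        limb = generate_limb(random_spec(int(s)))
        metrics, _ = measure_limb(limb.landmarks, limb.tibia, limb.mask)
        row = {"seed": int(s)}
        for f in METRIC_FIELDS:
            true, got = getattr(limb.truth, f), getattr(metrics, f)
            row[f"{f}_rel_err_pct"] = 100.0 * abs(got - true) / abs(true)
        rows.append(row)
    recovery = pd.DataFrame(rows)
    recovery.to_csv(OUT / "recovery.csv", index=False)
    worst = recovery.drop(columns="seed").max()
    print("noiseless recovery, worst relative error per metric (%):")
    print(worst.to_string(float_format="%.4f"))

    noisy = []
    for s in seeds:
        limb = generate_limb(random_spec(int(s), sigma=SIGMA_MM), with_mask=False)
        frame = build_frame(limb.landmarks)
        ma = moment_arm(
            transepicondylar_axis(limb.landmarks),
            extensor_line_of_action(limb.landmarks, frame),
        )
        noisy.append({
            "seed": int(s),
            "true_mm": limb.truth.moment_arm,
            "measured_mm": ma,
            "error_mm": ma - limb.truth.moment_arm,
            "abs_rel_err_pct": 100.0 * abs(ma - limb.truth.moment_arm) / limb.truth.moment_arm,
        })
    sens = pd.DataFrame(noisy)
    sens.to_csv(OUT / "moment_arm_sensitivity.csv", index=False)
    print(f"\nmoment arm under {SIGMA_MM} mm landmark noise (n={N_COHORT}):")
    print(f"  bias      {sens.error_mm.mean():+.3f} mm")
    print(f"  SD        {sens.error_mm.std(ddof=1):.3f} mm")
    print(f"  mean |err| {sens.abs_rel_err_pct.mean():.2f} %")
    print(f"  max  |err| {sens.abs_rel_err_pct.max():.2f} %")


if __name__ == "__main__":
    main()
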