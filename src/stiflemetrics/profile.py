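"""Per-limb metric aggregation into the study-style summary table.

With four limbs from two specimens the representative statistic is the
median (mean of the two central order statistics for even n) together
with the range (max - min).  Reporting rounding — one decimal, half away
from zero — is applied only when the table is serialized; JSON twins keep
full precision.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import StifleError
from .static_metrics import METRIC_FIELDS, LimbMetrics

#: Display captions, in table column order.
METRIC_CAPTIONS = {
    "tl": "TL (mm)",
    "fl": "FL (mm)",
    "flexion_angle": "Flexion Angle (deg)",
    "qca": "QCA (cm^2)",
    "qca_fl": "QCA.FL (cm^2.m)",
    "moment_arm": "Moment Arm (mm)",
    "tt_projection_index": "TT Projection Index",
    "tp_tt_ratio": "TP:TT Ratio",
    "pennation_vl": "Pennation Angle VL (deg)",
    "pennation_rf": "Pennation Angle RF (deg)",
}


def median(values) -> float:
    """Middle order statistic; mean of the two central ones for even n."""
    vals = sorted(float(v) for v in values)
    if not vals:
        raise ValueError("median of an empty list")
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def range_stat(values) -> float:
    """max - min."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("range of an empty list")
    return max(vals) - min(vals)


def round_report(x: float, decimals: int = 1) -> float:
    """Reporting rounding: half away from zero at ``decimals`` places.

    Values are first quantized at 1e-9 (half-even) to absorb binary float
    fuzz: the median of two one-decimal inputs such as 196.1 and 205.2 is
    200.64999999999998 in double precision but is meant to round as 200.65.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProfileSummary:
    """Per-metric median and range over n limbs (full precision)."""

    n: int
    medians: dict
    ranges: dict

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("summary needs >= 1 limb")
        for f in METRIC_FIELDS:
            if self.ranges[f] < 0:
                raise ValueError("negative range")


def summarize(limbs) -> ProfileSummary:
    """Median and range of every metric over the given limb profiles."""
    limbs = list(limbs)
    if not limbs:
        raise ValueError("summarize needs >= 1 limb")
    for lm in limbs:
        if not isinstance(lm, LimbMetrics):
            raise StifleError(f"expected LimbMetrics, got {type(lm).__name__}")
    cols = {f: [getattr(lm, f) for lm in limbs] for f in METRIC_FIELDS}
    return ProfileSummary(
        n=len(limbs),
        medians={f: median(v) for f, v in cols.items()},
        ranges={f: range_stat(v) for f, v in cols.items()},
    )


def profile_frame(limbs, summary: ProfileSummary | None = None, rounded: bool = True) -> pd.DataFrame:
    """The summary table as a DataFrame: one row per limb + Median + Range."""
    limbs = list(limbs)
    summary = summary or summarize(limbs)
    rows, index = [], []
    for i, lm in enumerate(limbs, start=1):
        rows.append([getattr(lm, f) for f in METRIC_FIELDS])
        index.append(f"Limb {i}")
    rows.append([summary.medians[f] for f in METRIC_FIELDS])
    index.append("Median")
    rows.append([summary.ranges[f] for f in METRIC_FIELDS])
    index.append("Range")
    df = pd.DataFrame(rows, index=index, columns=[METRIC_CAPTIONS[f] for f in METRIC_FIELDS])
    if rounded:
        df = df.map(round_report)
    return df


def write_profile(summary: ProfileSummary, limbs, out_dir, stem: str = "profile"):
    """Write the summary table as CSV (rounded) and JSON (full precision).

    Returns the (csv_path, json_path) pair.  The CSV has one row per limb
    followed by Median and Range rows, in the study's column order, with
    every cell rounded half-away-from-zero to one decimal; the JSON twin
    preserves full precision for downstream recomputation.
    """
    limbs = list(limbs)
    if not limbs:
        raise ValueError("write_profile needs >= 1 limb")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        json_path = out_dir / f"{stem}.json"
        df = profile_frame(limbs, summary, rounded=True)
        df.to_csv(csv_path, index_label="Limb", float_format="%.1f")
        payload = {
            "n": summary.n,
            "limbs": [lm.as_dict() for lm in limbs],
            "median": summary.medians,
            "range": summary.ranges,
        }
        json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    except OSError as exc:
        raise StifleError(f"cannot write profile under {out_dir}: {exc}") from exc
    return csv_path, json_path
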