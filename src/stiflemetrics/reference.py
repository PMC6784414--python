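"""Published reference values used as inputs and documentation constants.

``STUDY_LIMB_ROWS`` carries the printed per-limb static measurements for
the four *Macropus giganteus* hindlimbs (two specimens); it is the input
to the aggregation demonstrations, since no imaging data were deposited.
``HUMAN_COMPARATORS`` stores the human / Neanderthal / child comparison
values discussed alongside those results — documentation constants only;
no comparative statistics are computed from them here.
"""
from __future__ import annotations

from .static_metrics import LimbMetrics

#: Printed per-limb rows, in metric-field order (see METRIC_FIELDS):
#: tl, fl, flexion_angle, qca, qca_fl, moment_arm,
#: tt_projection_index, tp_tt_ratio, pennation_vl, pennation_rf.
STUDY_LIMB_ROWS = {
    "Limb 1": (395.5, 196.1, 78.2, 77.1, 15.1, 29.1, 15.3, 1.4, 32.1, 45.8),
    "Limb 2": (392.9, 189.9, 70.0, 81.6, 15.4, 28.6, 18.2, 1.9, 19.0, 20.8),
    "Limb 3": (418.9, 205.2, 68.4, 101.7, 20.9, 28.5, 17.8, 1.7, 24.8, 29.3),
    "Limb 4": (405.3, 209.2, 88.6, 86.1, 18.0, 32.2, 18.0, 1.8, 29.9, 27.9),
}

#: Printed Median row (same order), for cross-checking serialization.
STUDY_MEDIAN_ROW = (400.4, 200.7, 74.1, 83.9, 16.7, 28.9, 17.9, 1.8, 27.4, 28.6)

#: Printed Range row.  The FL (20.1) and Moment Arm (3.8) cells are not
#: reproducible from the printed limb values (which give 19.3 and 3.7);
#: they were presumably computed from unrounded measurements that were
#: not published, and are therefore excluded from exact cross-checks.
STUDY_RANGE_ROW = (26.0, 20.1, 20.2, 24.6, 5.8, 3.8, 2.9, 0.5, 13.1, 25.0)
RANGE_CELLS_NOT_REPRODUCIBLE = ("fl", "moment_arm")

#: Limb 2's printed QCA.FL (15.4) disagrees with 81.6 * 189.9 / 1000 =
#: 15.496 -> 15.5 at one decimal; excluded from the recomputation check.
QCA_FL_CELLS_NOT_REPRODUCIBLE = ("Limb 2",)

#: Human / Neanderthal / child comparison constants (documentation only).
HUMAN_COMPARATORS = {
    "moment_arm_mm": {
        "human_adult_cadaver": 50.0,
        "human_adult_in_vivo_mri": 45.0,
        "human_child": 37.0,
        "neanderthal": 32.0,
    },
    "tt_projection_index": {"human_adult_european": 10.3},
    "qca_fl_cm2m": {"human_men": 29.0, "human_women": 22.0, "boys_6_to_9": 9.4},
    "segment_length_mm": {"human_male_femur": 425.0, "human_male_tibia_asian_indian": 355.0},
}


def study_limbs() -> list[LimbMetrics]:
    """The four printed limb rows as :class:`LimbMetrics` objects."""
    return [LimbMetrics(*row) for row in STUDY_LIMB_ROWS.values()]
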