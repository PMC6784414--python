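"""End-to-end measurement of one limb: inputs in, ten-metric profile out."""
from __future__ import annotations

from .anatomy import LandmarkSet, build_frame
from .config import RunConfig
from .geometry import TriMesh
from .muscle_metrics import (
    VoxelMask,
    mean_csa,
    midfemur_slab,
    qca_fl,
    slice_areas,
    total_qca,
)
from .static_metrics import (
    LimbMetrics,
    assemble_limb_metrics,
    extensor_line_of_action,
    femoral_length,
    flexion_angle,
    moment_arm,
    moment_arm_torque_effective,
    pennation_from_landmarks,
    tibial_length,
    tp_tt_metrics,
    transepicondylar_axis,
)


def measure_limb(
    landmarks: LandmarkSet,
    tibia: TriMesh,
    mask: VoxelMask,
    femur: TriMesh | None = None,
    extensor: TriMesh | None = None,
    config: RunConfig | None = None,
    log=None,
):
    """Run every static measurement on one limb.

    The femur and extensor meshes are accepted for completeness (the
    measurements themselves are landmark- and tibia-mesh-driven; the
    extensor line of action comes from the extensor path points).  Returns
    ``(LimbMetrics, details)`` where ``details`` records every intermediate
    landmark, axis, plane and per-muscle series for auditability.
    """
    cfg = config or RunConfig()
    landmarks.validate()
    frame = build_frame(landmarks)

    fl = femoral_length(landmarks, frame)
    tl = tibial_length(landmarks, frame)
    flexion = flexion_angle(landmarks, frame)

    axis = transepicondylar_axis(landmarks)
    loa = extensor_line_of_action(landmarks, frame)
    ma = moment_arm(axis, loa)
    ma_torque = moment_arm_torque_effective(axis, loa)

    tptt = tp_tt_metrics(tibia, landmarks, frame, tl, cfg)

    slab = midfemur_slab(frame, landmarks, mask, config=cfg)
    series = {
        name: slice_areas(mask, code, slab)
        for name, code in mask.label_codes.items()
    }
    csa = {name: mean_csa(s) for name, s in series.items()}
    qca = total_qca(csa["RF"], csa["VL"], csa["VI"], csa["VM"])

    pen_vl = pennation_from_landmarks(landmarks, "vl")
    pen_rf = pennation_from_landmarks(landmarks, "rf")

    metrics = assemble_limb_metrics(
        tl=tl,
        fl=fl,
        flexion_angle=flexion,
        qca=qca,
        qca_fl=qca_fl(qca, fl),
        moment_arm=ma,
        tt_projection_index=tptt.tt_projection_index,
        tp_tt_ratio=tptt.tp_tt_ratio,
        pennation_vl=pen_vl,
        pennation_rf=pen_rf,
    )
    details = {
        "frame": {
            "origin": frame.origin.tolist(),
            "anterior": frame.anterior.tolist(),
            "proximal": frame.proximal.tolist(),
            "lateral": frame.lateral.tolist(),
        },
        "transepicondylar_axis": {
            "point": axis.point.tolist(),
            "direction": axis.direction.tolist(),
        },
        "line_of_action": {
            "point": loa.point.tolist(),
            "direction": loa.direction.tolist(),
        },
        "moment_arm_torque_effective_mm": ma_torque,
        "tp_tt": {"d1_mm": tptt.d1, "d2_mm": tptt.d2},
        "slab_slices": list(slab),
        "muscle_mean_csa_cm2": csa,
        "side": landmarks.side,
    }
    if log is not None:
        log.event("measure_limb", metrics=metrics.as_dict(), **details)
    return metrics, details
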