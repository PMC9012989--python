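"""Synthetic human-silhouette thermal phantoms and two-group cohorts.

Real whole-body thermograms cannot be redistributed, so every pipeline stage
is exercised on parametric phantoms instead: a polygonal front-view
silhouette (head, neck, trunk, two slightly-extended arms with palms) at
skin temperature over a cooler uniform room background, which reproduces the
structural facts the pipeline relies on — a bimodal global temperature
histogram, 12 plausible landmark positions, and 18 segmentable regions.

A cohort draws per-subject zone temperature offsets around fixed anatomical
baselines (warm clavicle fossae and face, cooler distal arms) and applies a
configurable face-zone shift to the case group, so the downstream
face-chest statistics see a known ground-truth effect. Generation is a pure
function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .roi_segmentation import AnchorSet
from .thermal_io import DEFAULT_COLS, DEFAULT_ROWS, TemperatureField

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "CohortSubject",
    "generate_phantom",
    "generate_cohort",
]

#: Baseline zone offsets in °C relative to the body base temperature.
#: Depressed areas (clavicle fossae) run warm, distal limbs run cool; the
#: whole-body spread stays within the few-degree range typical of skin.
DEFAULT_ZONE_OFFSETS = {
    "head": 1.2,
    "neck": 1.5,
    "chest": 0.5,
    "abdomen": 0.0,
    "upper_arm": -0.3,
    "forearm": -0.5,
    "palm": -1.0,
}

#: Between-subject SD of the head and chest zone offsets, °C. The two zones
#: vary independently, so a per-subject face-minus-chest mean difference has
#: SD sqrt(2) * 1.082 ≈ 1.53 °C.
DEFAULT_BETWEEN_SUBJECT_SD = 1.082

#: Between-subject SD of the remaining zones, °C. Kept tighter so the coolest
#: distal zones always stay clear of the ambient/skin histogram valley.
DEFAULT_LIMB_SD = 0.3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and temperature model of one phantom frame."""

    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    ambient_temp: float = 25.0        # °C, room background
    body_base_temp: float = 32.5      # °C, trunk baseline
    zone_offsets: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_OFFSETS))
    noise_sd: float = 0.25            # °C, per-pixel Gaussian noise

    def __post_init__(self) -> None:
        if self.rows < 64 or self.cols < 64:
            raise ParameterError("phantom needs at least 64x64 pixels")
        if self.noise_sd < 0:
            raise ParameterError("noise SD cannot be negative")
        if not self.ambient_temp < self.body_base_temp - 4:
            raise ParameterError(
                "ambient must sit at least 4 °C below the body base to guarantee bimodality"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with a known face-zone effect in the case group."""

    n_per_group: int = 43
    face_effect: float = 2.74         # °C added to the case group's head zone
    between_subject_sd: float = DEFAULT_BETWEEN_SUBJECT_SD
    limb_sd: float = DEFAULT_LIMB_SD  # SD of the non-face, non-chest zones
    global_shift_sd: float = 0.3      # whole-body per-subject shift (cancels in ΔT)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 subjects per group")
        if self.between_subject_sd < 0 or self.limb_sd < 0 or self.global_shift_sd < 0:
            raise ParameterError("SDs cannot be negative")


@dataclass
class Phantom:
    """One generated frame with its ground truth."""

    fld: TemperatureField
    anchors: AnchorSet
    body_mask: np.ndarray             # True on silhouette pixels
    zone_masks: dict[str, np.ndarray]


@dataclass
class CohortSubject:
    subject_id: str
    group: str                        # "case" | "control"
    phantom: Phantom
    zone_offsets: dict[str, float]    # realized per-subject offsets


def _layout(spec: PhantomSpec) -> dict:
    """Pixel geometry of the silhouette, scaled to the frame."""
    R, C = spec.rows, spec.cols
    m = C // 2
    lay = {
        "mid": m,
        "head_center": (int(0.12 * R), m),
        "head_ry": int(0.085 * R),
        "head_rx": int(0.055 * C),
        "shoulder_row": int(0.26 * R),
        "armpit_row": int(0.31 * R),
        "elbow_row": int(0.43 * R),
        "wrist_row": int(0.60 * R),
        "palm_bottom": int(0.655 * R),
        "belly_row": int(0.62 * R),
        "crotch_row": int(0.78 * R),
        "torso_hw": int(0.16 * C),
        "neck_hw": int(0.03 * C),
        "arm_gap": int(0.02 * C),
        "arm_w": int(0.045 * C),
    }
    lay["chin_row"] = lay["head_center"][0] + lay["head_ry"]
    lay["forehead_row"] = lay["head_center"][0] - int(0.6 * lay["head_ry"])
    return lay


def _zone_masks(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    R, C = spec.rows, spec.cols
    lay = _layout(spec)
    m = lay["mid"]
    rr, cc = np.mgrid[0:R, 0:C]

    hr, hc = lay["head_center"]
    head = ((rr - hr) / lay["head_ry"]) ** 2 + ((cc - hc) / lay["head_rx"]) ** 2 <= 1.0

    neck = (
        (rr > lay["chin_row"]) & (rr < lay["shoulder_row"])
        & (np.abs(cc - m) <= lay["neck_hw"])
    )

    torso = (
        (rr >= lay["shoulder_row"]) & (rr <= lay["crotch_row"])
        & (np.abs(cc - m) <= lay["torso_hw"])
    )
    chest_bottom = (lay["armpit_row"] + lay["belly_row"]) // 2
    chest = torso & (rr <= chest_bottom)
    abdomen = torso & (rr > chest_bottom)

    arm_in = lay["torso_hw"] + lay["arm_gap"]
    arm_out = arm_in + lay["arm_w"]
    arm_band = ((cc <= m - arm_in) & (cc >= m - arm_out)) | (
        (cc >= m + arm_in) & (cc <= m + arm_out)
    )
    # shoulder bridge joins arm to trunk down to the armpit row
    bridge = (
        (rr >= lay["shoulder_row"]) & (rr <= lay["armpit_row"])
        & (np.abs(cc - m) > lay["torso_hw"]) & (np.abs(cc - m) <= arm_out)
    )
    upper_arm = (arm_band & (rr > lay["armpit_row"]) & (rr <= lay["elbow_row"])) | bridge
    forearm = arm_band & (rr > lay["elbow_row"]) & (rr <= lay["wrist_row"])
    palm = arm_band & (rr > lay["wrist_row"]) & (rr <= lay["palm_bottom"])

    zones = {
        "head": head,
        "neck": neck,
        "chest": chest,
        "abdomen": abdomen,
        "upper_arm": upper_arm,
        "forearm": forearm,
        "palm": palm,
    }
    body = np.zeros((R, C), dtype=bool)
    for msk in zones.values():
        body |= msk
    return body, zones


def _anchors(spec: PhantomSpec) -> AnchorSet:
    lay = _layout(spec)
    m = lay["mid"]
    arm_center = lay["torso_hw"] + lay["arm_gap"] + lay["arm_w"] // 2
    pts = {
        "Pur_1": (lay["wrist_row"], m - arm_center),             # right wrist
        "Pur_2": (lay["elbow_row"], m - arm_center),             # medial right elbow
        "Pur_3": (lay["armpit_row"], m - lay["torso_hw"] - lay["arm_gap"] // 2 - 1),
        "Pur_4": (lay["shoulder_row"] + 2, m - lay["torso_hw"] + 2),
        "Pur_5": (lay["wrist_row"], m + arm_center),             # left wrist
        "Pur_6": (lay["elbow_row"], m + arm_center),
        "Pur_7": (lay["armpit_row"], m + lay["torso_hw"] + lay["arm_gap"] // 2 + 1),
        "Pur_8": (lay["shoulder_row"] + 2, m + lay["torso_hw"] - 2),
        "Pur_9": (lay["forehead_row"], m),                       # forehead
        "Pur_10": (lay["chin_row"], m),                          # chin
        "Pur_11": (lay["belly_row"], m),                         # belly-button
        "Pur_12": (lay["crotch_row"] - 1, m),                    # crotch
    }
    return AnchorSet(pts)


def generate_phantom(
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    zone_shifts: dict[str, float] | None = None,
) -> Phantom:
    """Render one phantom frame.

    ``zone_shifts`` adds per-zone °C offsets on top of the spec's baseline
    offsets (used by :func:`generate_cohort` for subject effects). With
    ``noise_sd=0`` every zone is exactly ``body_base + offset``.
    """
    unknown = set(spec.zone_offsets) - set(DEFAULT_ZONE_OFFSETS)
    if unknown:
        raise ParameterError(f"unknown zones in spec: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    body, zones = _zone_masks(spec)
    vals = np.full((spec.rows, spec.cols), spec.ambient_temp, dtype=np.float64)
    shifts = zone_shifts or {}
    for name, msk in zones.items():
        vals[msk] = spec.body_base_temp + spec.zone_offsets.get(name, 0.0) + shifts.get(name, 0.0)
    if spec.noise_sd > 0:
        vals += rng.normal(0.0, spec.noise_sd, size=vals.shape)
    return Phantom(
        fld=TemperatureField(vals),
        anchors=_anchors(spec),
        body_mask=body,
        zone_masks=zones,
    )


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0) -> list[CohortSubject]:
    """Generate the case and control groups (default 43 + 43 subjects).

    Each subject gets independent zone offsets — N(0, between_subject_sd)
    for the head and chest zones that carry the ΔT features, N(0, limb_sd)
    elsewhere — plus one whole-body shift ~ N(0, global_shift_sd); case
    subjects additionally receive ``face_effect`` on the head zone.
    Deterministic in (spec, seed).
    """
    master = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    for group in ("control", "case"):
        for i in range(spec.n_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            shifts = {
                z: float(
                    rng.normal(
                        0.0,
                        spec.between_subject_sd if z in ("head", "chest") else spec.limb_sd,
                    )
                )
                for z in DEFAULT_ZONE_OFFSETS
            }
            g = float(rng.normal(0.0, spec.global_shift_sd))
            shifts = {z: v + g for z, v in shifts.items()}
            if group == "case":
                shifts["head"] += spec.face_effect
            phantom = generate_phantom(spec.phantom, seed=sub_seed + 1, zone_shifts=shifts)
            subjects.append(
                CohortSubject(
                    subject_id=f"{group}_{i + 1:02d}",
                    group=group,
                    phantom=phantom,
                    zone_offsets=shifts,
                )
            )
    return subjects
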