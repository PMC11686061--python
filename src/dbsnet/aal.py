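"""AAL-90 region labels and the bilateral motor subnetwork.

The 90-region parcellation covers the cerebrum only (vermis and cerebellum
excluded), left/right interleaved in the standard AAL numbering. The motor
subnetwork comprises seven bilateral regions of the basal ganglia-
thalamo-cortical circuit: precentral gyrus, supplementary motor area,
postcentral gyrus, caudate, putamen, pallidum, and thalamus (14 ROIs).
The subthalamic nucleus itself is below the spatial reach of scalp source
reconstruction and is not an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

AAL90_LABELS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)

# Cortical regions first (precentral, SMA, postcentral), subcortical after —
# the ordering used throughout loading-matrix reports.
MOTOR_LABELS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Postcentral_L", "Postcentral_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
)

MOTOR_CORTICAL_COUNT = 6  # first six of MOTOR_LABELS are cortical


@dataclass(frozen=True)
class MotorROISet:
    """The 14-region motor subnetwork resolved against a full ROI label list."""

    labels: tuple[str, ...]
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.indices):
            raise ValueError("labels and indices must have equal length")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("motor ROI indices must be distinct")

    @classmethod
    def from_labels(
        cls,
        roi_labels: "list[str] | tuple[str, ...]",
        motor_labels: tuple[str, ...] = MOTOR_LABELS,
    ) -> "MotorROISet":
        indices = []
        for lab in motor_labels:
            try:
                indices.append(roi_labels.index(lab))  # type: ignore[union-attr]
            except ValueError:
                raise KeyError(
                    f"motor ROI label {lab!r} not found in the ROI label list"
                ) from None
        return cls(labels=tuple(motor_labels), indices=tuple(indices))


# Lobe groups used for matrix-figure ordering: frontal (Fr), cingulate (Ci),
# mesiotemporal (Me), occipital (Oc), parietal (Pa), subcortical (Su),
# temporal (Te). Assignment is by region-name prefix; the insula is grouped
# with the subcortical block.
_LOBE_PREFIXES: tuple[tuple[str, str], ...] = (
    ("Precentral", "Fr"), ("Frontal_", "Fr"), ("Rolandic_Oper", "Fr"),
    ("Supp_Motor_Area", "Fr"), ("Olfactory", "Fr"), ("Rectus", "Fr"),
    ("Paracentral_Lobule", "Fr"),
    ("Cingulum_", "Ci"),
    ("Hippocampus", "Me"), ("ParaHippocampal", "Me"), ("Amygdala", "Me"),
    ("Calcarine", "Oc"), ("Cuneus", "Oc"), ("Lingual", "Oc"),
    ("Occipital_", "Oc"), ("Fusiform", "Oc"),
    ("Postcentral", "Pa"), ("Parietal_", "Pa"), ("SupraMarginal", "Pa"),
    ("Angular", "Pa"), ("Precuneus", "Pa"),
    ("Insula", "Su"), ("Caudate", "Su"), ("Putamen", "Su"),
    ("Pallidum", "Su"), ("Thalamus", "Su"),
    ("Heschl", "Te"), ("Temporal_", "Te"),
)

LOBE_ORDER = ("Fr", "Ci", "Me", "Oc", "Pa", "Su", "Te")


def lobe_of(label: str) -> str:
    for prefix, lobe in _LOBE_PREFIXES:
        if label.startswith(prefix):
            return lobe
    raise KeyError(f"no lobe group for ROI label {label!r}")


def hemisphere_lobe_ordering(
    roi_labels: tuple[str, ...] = AAL90_LABELS,
) -> list[int]:
    """ROI permutation for matrix figures: left hemisphere first, then right,
    lobes grouped Fr, Ci, Me, Oc, Pa, Su, Te within each hemisphere."""

    def key(i: int):
        lab = roi_labels[i]
        hemi = 0 if lab.endswith("_L") else 1
        return (hemi, LOBE_ORDER.index(lobe_of(lab)), lab)

    return sorted(range(len(roi_labels)), key=key)


def motor_indices_for(roi_count: int) -> tuple[int, ...]:
    """Default motor-subnetwork indices for a parcellation of ``roi_count`` ROIs.

    For the full 90-ROI atlas these are the true AAL positions; for reduced
    synthetic parcellations (used to keep simulations small) the first 14
    indices stand in, preserving the cortical/subcortical split.
    """
    if roi_count >= 90:
        return MotorROISet.from_labels(list(AAL90_LABELS)).indices
    if roi_count < 14:
        raise ValueError("need at least 14 ROIs for a motor subnetwork")
    return tuple(range(14))
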