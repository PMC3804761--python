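"""Static lookup: AAL-116 region names and a coarse functional-network map.

The automatic anatomical labeling (AAL) atlas parcellates the cerebrum into
90 regions and the cerebellum into 26 (9 per hemisphere plus 8 vermal).
Region numbering in reports is 1-based in this canonical order; internal
indices are 0-based.

The network membership (cingulo-opercular CON, default-mode DMN, visual,
sensorimotor, frontal-parietal, cerebellum, other) is shipped as editable
*data*, not computed: it is the conventional coarse assignment used when
summarizing which systems a consensus network touches, and users with a
different taxonomy can override it.
"""

from __future__ import annotations

__all__ = ["AAL116_LABELS", "network_of", "NETWORKS"]

_BILATERAL = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]
_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

#: the 116 region labels in canonical atlas order (L before R)
AAL116_LABELS: tuple[str, ...] = tuple(
    f"{base}_{side}" for base in _BILATERAL for side in ("L", "R")
) + tuple(_VERMIS)

_NETWORK_BY_BASE = {
    # default-mode network
    "Frontal_Sup_Medial": "DMN", "Frontal_Med_Orb": "DMN", "Rectus": "DMN",
    "Cingulum_Post": "DMN", "Hippocampus": "DMN", "ParaHippocampal": "DMN",
    "Angular": "DMN", "Precuneus": "DMN", "Temporal_Mid": "DMN",
    # cingulo-opercular network
    "Insula": "CON", "Cingulum_Ant": "CON", "Cingulum_Mid": "CON",
    "Thalamus": "CON", "Caudate": "CON", "Putamen": "CON", "Pallidum": "CON",
    "Frontal_Inf_Oper": "CON", "Rolandic_Oper": "CON", "Parietal_Inf": "CON",
    # visual network
    "Calcarine": "visual", "Cuneus": "visual", "Lingual": "visual",
    "Occipital_Sup": "visual", "Occipital_Mid": "visual",
    "Occipital_Inf": "visual", "Fusiform": "visual",
    # sensorimotor network
    "Precentral": "sensorimotor", "Postcentral": "sensorimotor",
    "Supp_Motor_Area": "sensorimotor", "Paracentral_Lobule": "sensorimotor",
    "Heschl": "sensorimotor",
    # frontal-parietal network
    "Frontal_Sup": "frontal-parietal", "Frontal_Mid": "frontal-parietal",
    "Parietal_Sup": "frontal-parietal", "SupraMarginal": "frontal-parietal",
}

NETWORKS = (
    "CON", "DMN", "cerebellum", "visual", "sensorimotor", "frontal-parietal",
    "other",
)


def network_of(region_label: str) -> str:
    """Coarse functional-network membership of an AAL region label."""
    if region_label.startswith(("Cerebelum", "Vermis")):
        return "cerebellum"
    base = region_label
    if base.endswith(("_L", "_R")):
        base = base[:-2]
    return _NETWORK_BY_BASE.get(base, "other")
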