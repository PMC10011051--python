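"""Parcellation bookkeeping: node labels, abbreviations and plotting coordinates.

The default atlas is the 116-region AAL-style parcellation (90 cerebral
regions plus 18 cerebellar hemispheric regions and 8 vermis segments) that
whole-brain connectome studies commonly use.  Any other node count is
accepted for analysis; the bundled label table only matters for reporting
and for ball-and-stick export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Atlas", "aal116", "AAL116_BASE_NAMES", "ABBREVIATIONS"]

# Bilateral region base names in conventional AAL order (suffixed _L/_R).
AAL116_BASE_NAMES = [
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
]

_CEREBELLUM_BASE_NAMES = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]

_VERMIS_NAMES = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

# Short names of the style used in connectome figures (PreCG, PoCG, INS ...).
ABBREVIATIONS = {
    "Precentral": "PreCG", "Frontal_Sup": "SFG", "Frontal_Sup_Orb": "ORBsup",
    "Frontal_Mid": "MFG", "Frontal_Mid_Orb": "ORBmid",
    "Frontal_Inf_Oper": "IFGoperc", "Frontal_Inf_Tri": "IFGtriang",
    "Frontal_Inf_Orb": "ORBinf", "Rolandic_Oper": "ROL",
    "Supp_Motor_Area": "SMA", "Olfactory": "OLF",
    "Frontal_Sup_Medial": "SFGmed", "Frontal_Med_Orb": "ORBsupmed",
    "Rectus": "REC", "Insula": "INS", "Cingulum_Ant": "ACG",
    "Cingulum_Mid": "DCG", "Cingulum_Post": "PCG", "Hippocampus": "HIP",
    "ParaHippocampal": "PHG", "Amygdala": "AMYG", "Calcarine": "CAL",
    "Cuneus": "CUN", "Lingual": "LING", "Occipital_Sup": "SOG",
    "Occipital_Mid": "MOG", "Occipital_Inf": "IOG", "Fusiform": "FFG",
    "Postcentral": "PoCG", "Parietal_Sup": "SPG", "Parietal_Inf": "IPL",
    "SupraMarginal": "SMG", "Angular": "ANG", "Precuneus": "PCUN",
    "Paracentral_Lobule": "PCL", "Caudate": "CAU", "Putamen": "PUT",
    "Pallidum": "PAL", "Thalamus": "THA", "Heschl": "HES",
    "Temporal_Sup": "STG", "Temporal_Pole_Sup": "TPOsup",
    "Temporal_Mid": "MTG", "Temporal_Pole_Mid": "TPOmid",
    "Temporal_Inf": "ITG",
    "Cerebelum_Crus1": "CRBLCrus1", "Cerebelum_Crus2": "CRBLCrus2",
    "Cerebelum_3": "CRBL3", "Cerebelum_4_5": "CRBL45", "Cerebelum_6": "CRBL6",
    "Cerebelum_7b": "CRBL7b", "Cerebelum_8": "CRBL8", "Cerebelum_9": "CRBL9",
    "Cerebelum_10": "CRBL10",
    "Vermis_1_2": "Ver12", "Vermis_3": "Ver3", "Vermis_4_5": "Ver45",
    "Vermis_6": "Ver6", "Vermis_7": "Ver7", "Vermis_8": "Ver8",
    "Vermis_9": "Ver9", "Vermis_10": "Ver10",
}


def _aal116_labels() -> list[str]:
    labels: list[str] = []
    for base in AAL116_BASE_NAMES:
        labels += [base + "_L", base + "_R"]
    for base in _CEREBELLUM_BASE_NAMES:
        labels += [base + "_L", base + "_R"]
    labels += list(_VERMIS_NAMES)
    return labels


@dataclass
class Atlas:
    """An M-node parcellation: unique labels and optional 3-D coordinates.

    ``coordinates`` (M x 3, MNI-like millimetres) are only needed for
    ball-and-stick export; analysis never touches them.
    """

    labels: list[str]
    coordinates: np.ndarray | None = None
    abbreviations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.labels), 3):
                raise ValueError(
                    f"coordinates must be ({len(self.labels)}, 3), "
                    f"got {self.coordinates.shape}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def abbreviation(self, node: int) -> str:
        label = self.labels[node]
        base = label[:-2] if label.endswith(("_L", "_R")) else label
        side = label[-1] if label.endswith(("_L", "_R")) else ""
        abbr = self.abbreviations.get(base, base)
        return f"{abbr}.{side}" if side else abbr

    @classmethod
    def generic(cls, n_nodes: int) -> "Atlas":
        """A nameless atlas (node_000 ...) for arbitrary node counts."""
        width = max(3, len(str(n_nodes - 1)))
        return cls(labels=[f"node_{i:0{width}d}" for i in range(n_nodes)])


def _synthetic_coordinates(n: int) -> np.ndarray:
    # Synthetic placeholder centroids inside a brain-sized bounding box;
    # deterministic, for plotting layout only -- these are NOT measured
    # MNI centroids of any published parcellation.
    rng = np.random.default_rng(116)
    xyz = np.empty((n, 3))
    xyz[:, 0] = rng.uniform(-65, 65, n)   # left-right
    xyz[:, 1] = rng.uniform(-95, 65, n)   # posterior-anterior
    xyz[:, 2] = rng.uniform(-45, 70, n)   # inferior-superior
    # mirror bilateral pairs (even=left, odd=right) for a symmetric layout
    for i in range(0, min(n - 1, 107), 2):
        xyz[i, 0] = -abs(xyz[i, 0])
        xyz[i + 1] = xyz[i] * np.array([-1.0, 1.0, 1.0])
    return np.round(xyz, 2)


def aal116() -> Atlas:
    """The bundled 116-label AAL-style atlas with synthetic plot coordinates."""
    labels = _aal116_labels()
    return Atlas(
        labels=labels,
        coordinates=_synthetic_coordinates(len(labels)),
        abbreviations=dict(ABBREVIATIONS),
    )
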