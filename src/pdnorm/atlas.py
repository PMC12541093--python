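"""Region name lists for the cortical (Destrieux, 148) and subcortical (aseg, 37) atlases.

Measure columns in a cohort table are named ``<hemi>_<region>_thickness`` for
the 74 Destrieux parcels per hemisphere and ``<structure>_volume`` for the 37
subcortical structures, mirroring FreeSurfer regional-stats exports.
"""

from __future__ import annotations

DESTRIEUX_REGIONS: tuple[str, ...] = (
    "G_and_S_frontomargin", "G_and_S_occipital_inf", "G_and_S_paracentral",
    "G_and_S_subcentral", "G_and_S_transv_frontopol", "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant", "G_and_S_cingul-Mid-Post", "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral", "G_cuneus", "G_front_inf-Opercular",
    "G_front_inf-Orbital", "G_front_inf-Triangul", "G_front_middle",
    "G_front_sup", "G_Ins_lg_and_S_cent_ins", "G_insular_short",
    "G_occipital_middle", "G_occipital_sup", "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual", "G_oc-temp_med-Parahip", "G_orbital",
    "G_pariet_inf-Angular", "G_pariet_inf-Supramar", "G_parietal_sup",
    "G_postcentral", "G_precentral", "G_precuneus", "G_rectus",
    "G_subcallosal", "G_temp_sup-G_T_transv", "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar", "G_temp_sup-Plan_tempo", "G_temporal_inf",
    "G_temporal_middle", "Lat_Fis-ant-Horizont", "Lat_Fis-ant-Vertical",
    "Lat_Fis-post", "Pole_occipital", "Pole_temporal", "S_calcarine",
    "S_central", "S_cingul-Marginalis", "S_circular_insula_ant",
    "S_circular_insula_inf", "S_circular_insula_sup", "S_collat_transv_ant",
    "S_collat_transv_post", "S_front_inf", "S_front_middle", "S_front_sup",
    "S_interm_prim-Jensen", "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus", "S_oc_sup_and_transversal", "S_occipital_ant",
    "S_oc-temp_lat", "S_oc-temp_med_and_Lingual", "S_orbital_lateral",
    "S_orbital_med-olfact", "S_orbital-H_Shaped", "S_parieto_occipital",
    "S_pericallosal", "S_postcentral", "S_precentral-inf-part",
    "S_precentral-sup-part", "S_suborbital", "S_subparietal",
    "S_temporal_inf", "S_temporal_sup", "S_temporal_transverse",
)

_ASEG_BILATERAL: tuple[str, ...] = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "vessel",
    "choroid-plexus",
)

_ASEG_MIDLINE: tuple[str, ...] = (
    "3rd-Ventricle", "4th-Ventricle", "Brain-Stem", "CSF", "Optic-Chiasm",
    "CC_Posterior", "CC_Mid_Posterior", "CC_Central", "CC_Mid_Anterior",
)

ASEG_STRUCTURES: tuple[str, ...] = tuple(
    f"{side}-{name}" for side in ("Left", "Right") for name in _ASEG_BILATERAL
) + _ASEG_MIDLINE

THICKNESS_COLUMNS: tuple[str, ...] = tuple(
    f"{hemi}_{region}_thickness"
    for hemi in ("lh", "rh")
    for region in DESTRIEUX_REGIONS
)

VOLUME_COLUMNS: tuple[str, ...] = tuple(f"{s}_volume" for s in ASEG_STRUCTURES)

#: all 185 measure columns, cortical first
ROI_COLUMNS: tuple[str, ...] = THICKNESS_COLUMNS + VOLUME_COLUMNS

assert len(THICKNESS_COLUMNS) == 148
assert len(VOLUME_COLUMNS) == 37

# subcortical structures given a stronger planted disease effect in the
# synthetic cohort (basal-ganglia focus of PD atrophy)
FOCUS_STRUCTURES: tuple[str, ...] = (
    "Left-Caudate_volume", "Right-Caudate_volume",
    "Left-Putamen_volume", "Right-Putamen_volume",
)


def is_volume(column: str) -> bool:
    return column.endswith("_volume")


def is_thickness(column: str) -> bool:
    return column.endswith("_thickness")
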