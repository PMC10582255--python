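"""Default region-of-interest and motor-item configuration.

The 40 motor-related ROI labels below are AAL3 parcels covering the
cortical sensorimotor strip, supplementary motor cortex, basal ganglia,
motor thalamic subdivisions, midbrain dopaminergic nuclei and motor
cerebellum.  They are configuration, not code: every pipeline entry point
accepts a user-supplied ROI list, and this default is only a stand-in for
a site's own atlas export.

The motor-examination item table maps each symptom family of the
MDS-UPDRS-III to its item identifiers (each lateralized or per-limb
sub-item is a separate key, e.g. ``3.3_neck``, ``3.4_R``).  The total
score is the sum over all 33 items.
"""

from __future__ import annotations

DEFAULT_MOTOR_ROIS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Postcentral_L", "Postcentral_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thal_VA_L", "Thal_VA_R",
    "Thal_VL_L", "Thal_VL_R",
    "Thal_VPL_L", "Thal_VPL_R",
    "Red_N_L", "Red_N_R",
    "SN_pc_L", "SN_pc_R",
    "SN_pr_L", "SN_pr_R",
    "Cerebellum_4_5_L", "Cerebellum_4_5_R",
    "Cerebellum_6_L", "Cerebellum_6_R",
    "Cerebellum_8_L", "Cerebellum_8_R",
    "Cerebellum_9_L", "Cerebellum_9_R",
    "Vermis_4_5", "Vermis_6", "Vermis_8", "Vermis_9",
)

# MDS-UPDRS part III item identifiers.  Lateralized items carry a suffix.
_LIMBS = ("neck", "RUE", "LUE", "RLE", "LLE")
_SIDES = ("R", "L")

ITEM_IDS: tuple[str, ...] = (
    "3.1", "3.2",
    *[f"3.3_{s}" for s in _LIMBS],
    *[f"3.4_{s}" for s in _SIDES],
    *[f"3.5_{s}" for s in _SIDES],
    *[f"3.6_{s}" for s in _SIDES],
    *[f"3.7_{s}" for s in _SIDES],
    *[f"3.8_{s}" for s in _SIDES],
    "3.9", "3.10", "3.11", "3.12", "3.13", "3.14",
    *[f"3.15_{s}" for s in _SIDES],
    *[f"3.16_{s}" for s in _SIDES],
    *[f"3.17_{s}" for s in _LIMBS],
    "3.18",
)

SUBSCORE_ITEMS: dict[str, tuple[str, ...]] = {
    "rigidity": tuple(f"3.3_{s}" for s in _LIMBS),
    "bradykinesia": tuple(
        f"3.{n}_{s}" for n in (4, 5, 6, 7, 8) for s in _SIDES
    ),
    "pig": ("3.10", "3.11", "3.12", "3.13"),
    "postural_kinetic": tuple(f"3.{n}_{s}" for n in (15, 16) for s in _SIDES),
    "rest": tuple(f"3.17_{s}" for s in _LIMBS),
}

SUBSCORE_NAMES: tuple[str, ...] = tuple(SUBSCORE_ITEMS)

#: items belonging to no subscore family (speech, facial expression, arising
#: from chair, posture, and constancy of rest tremor)
OTHER_ITEMS: tuple[str, ...] = tuple(
    i for i in ITEM_IDS
    if not any(i in v for v in SUBSCORE_ITEMS.values())
)
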