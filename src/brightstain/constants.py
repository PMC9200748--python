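"""Canonical channel ordering shared by every module.

Fluorescent Cell Painting channels, in the fixed order used throughout:
DNA (nuclei), ER (endoplasmic reticulum), RNA (nucleoli / cytoplasmic RNA),
AGP (actin, Golgi, plasma membrane), Mito (mitochondria).

Brightfield planes are a transmitted-light z-stack: 4 µm below focus,
in focus, 4 µm above focus.
"""

FLUOR_CHANNELS = ("DNA", "ER", "RNA", "AGP", "Mito")
BRIGHTFIELD_PLANES = ("BF_zminus4", "BF_z0", "BF_zplus4")
N_FLUOR = len(FLUOR_CHANNELS)
N_BRIGHTFIELD = len(BRIGHTFIELD_PLANES)

ALL_CHANNELS = BRIGHTFIELD_PLANES + FLUOR_CHANNELS

COMPARTMENTS = ("cell", "cytoplasm", "nuclei")
FEATURE_TYPES = (
    "area_shape",
    "colocalization",
    "granularity",
    "intensity",
    "neighbors",
    "radial_distribution",
    "texture",
)
ROLES = ("negative_control", "positive_control", "treatment")
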