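"""Canonical names for the 18 cerebellar regions of interest.

Seven lobule pairs reported per hemisphere (Crus II and lobule VIIB as one
composite), three vermal composites, and cerebellar white matter.
"""

LATERALIZED_BASES = (
    "lobules_I_V",
    "lobule_VI",
    "crus_I",
    "crus_II_VIIB",
    "lobule_VIII",
    "lobule_IX",
    "lobule_X",
)
MIDLINE_ROIS = ("vermis_I_V", "vermis_VI_VII", "vermis_VIII_X", "white_matter")
ROI_NAMES: tuple[str, ...] = tuple(
    f"{side}_{base}" for side in ("left", "right") for base in LATERALIZED_BASES
) + MIDLINE_ROIS
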