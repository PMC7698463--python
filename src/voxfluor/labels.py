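"""Tissue label codes shared by every module.

The medium is a 3-D grid of integer labels.  Code 0 (``OUTSIDE``) is the
non-scattering ambient (air); codes 1-4 are scattering tissues with entries
in the optical-property table.
"""

from enum import IntEnum


class TissueLabel(IntEnum):
    OUTSIDE = 0
    SKIN = 1
    FAT = 2
    DUCT = 3
    CANCER = 4


#: canonical label map written to volume sidecars
LABEL_NAMES = {int(t): t.name.lower() for t in TissueLabel}

#: tissues that have optical properties (everything but ambient air)
INTERIOR_TISSUES = (
    TissueLabel.SKIN,
    TissueLabel.FAT,
    TissueLabel.DUCT,
    TissueLabel.CANCER,
)
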