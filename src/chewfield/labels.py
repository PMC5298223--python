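"""Closed tissue-label enumeration shared by the phantom and the FEM solver.

Label codes are stable small integers so that labeled volumes round-trip
through int16 NIfTI without remapping. ``BACKGROUND`` (0) marks voxels that
carry no finite element (air outside the head).
"""

from __future__ import annotations

from enum import IntEnum


class Tissue(IntEnum):
    BACKGROUND = 0
    SOFT_TISSUE = 1
    SKULL = 2
    CSF = 3
    GRAY = 4
    WHITE = 5
    MUSCLE = 6
    INTERNAL_AIR = 7
    BLOOD = 8
    FORAMEN_FILL = 9      # skull-base channel, blood + nerve average
    GRID_INSULATOR = 10   # silicone substrate of a subdural electrode grid
    DEFECT_FILL = 11      # CSF-filled craniotomy defect (burr hole / saw line)


#: Labels that may legally appear in a phantom volume.
ALL_TISSUES = frozenset(Tissue)

#: Labels whose voxels become finite elements (everything but background).
CONDUCTIVE_TISSUES = frozenset(t for t in Tissue if t is not Tissue.BACKGROUND)
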