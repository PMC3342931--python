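"""Cell-type codes shared by the lattice engine and the retina builder.

The lattice stores one generalized-cell ID per voxel; each cell carries one
of these type codes.  ``MEDIUM`` (0) is the extracellular fluid that fills
space not claimed by a cell or a Bruch's-membrane block.
"""

from __future__ import annotations

import numpy as np

MEDIUM = 0
VASCULAR = 1  # quiescent endothelial cell of the choriocapillaris
STALK = 2     # proliferative activated endothelial cell
TIP = 3       # transient matrix-degrading endothelial phenotype (24 h)
RPE = 4       # retinal pigment epithelium cell
POS = 5       # photoreceptor outer segment compartment
PIS = 6       # photoreceptor inner segment compartment
BRM = 7       # Bruch's membrane block (frozen solid material)

N_TYPES = 8

TYPE_NAMES = {
    MEDIUM: "Medium",
    VASCULAR: "Vascular",
    STALK: "Stalk",
    TIP: "Tip",
    RPE: "RPE",
    POS: "POS",
    PIS: "PIS",
    BRM: "BrM",
}

NAME_TO_TYPE = {v: k for k, v in TYPE_NAMES.items()}

#: endothelial-cell types (used by contact-inhibited chemotaxis and growth)
EC_TYPES = (VASCULAR, STALK, TIP)

EC_MASK = np.zeros(N_TYPES, dtype=np.uint8)
EC_MASK[list(EC_TYPES)] = 1
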