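"""Small published reference datasets used in examples and checks."""

from __future__ import annotations

import numpy as np

from .accuracy_assessment import ConfusionMatrix
from .raster_io import Legend

__all__ = ["CA_MAU_CLASSES", "CA_MAU_LEGEND", "ca_mau_confusion"]

#: Land-cover classes of the Mui Ca Mau mangrove classification:
#: four mangrove types (R. apiculata, A. alba and the two mixed stands),
#: aquaculture land and settlement.
CA_MAU_CLASSES = ("Rnmd", "Rnmm", "Rnmhgdm", "Rnmhgmd", "Ntts", "Dt")

CA_MAU_LEGEND = Legend(
    entries=(
        (1, "Rnmd", True),      # R. apiculata
        (2, "Rnmm", True),      # A. alba
        (3, "Rnmhgdm", True),   # mixed R. apiculata - A. alba
        (4, "Rnmhgmd", True),   # mixed A. alba - R. apiculata
        (5, "Ntts", False),     # aquaculture land
        (6, "Dt", False),       # settlement area
    ),
    nodata_code=0,
)

# published validation counts for the Ca Mau SPOT classification
# (222 check pixels; rows = reference, columns = predicted)
_CA_MAU_COUNTS = np.array(
    [
        [47, 7, 3, 0, 0, 0],
        [1, 18, 6, 0, 0, 0],
        [2, 3, 34, 4, 1, 4],
        [0, 0, 5, 13, 1, 5],
        [0, 0, 1, 1, 28, 0],
        [0, 0, 5, 4, 0, 29],
    ],
    dtype=np.int64,
)


def ca_mau_confusion() -> ConfusionMatrix:
    """The published 6-class validation confusion matrix (total 222)."""
    return ConfusionMatrix(counts=_CA_MAU_COUNTS.copy(), class_order=CA_MAU_CLASSES)
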