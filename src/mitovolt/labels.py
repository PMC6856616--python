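"""Compartment label vocabulary shared by simulator and analysis."""

from enum import IntEnum


class Compartment(IntEnum):
    """Per-pixel compartment classes.

    The same integer codes are used for simulator ground truth and for
    analysis label maps, so the two can be compared pixelwise.
    """

    BACKGROUND = 0
    CYTOSOL = 1
    MATRIX = 2
    IBM = 3
    CRISTA = 4
    VESICLE = 5


#: Labels that belong to the mitochondrion proper.
MITO_LABELS = (Compartment.MATRIX, Compartment.IBM, Compartment.CRISTA, Compartment.VESICLE)

#: Indexed-palette colors for label TIFF/PNG export (RGB, 0-255).
LABEL_PALETTE = {
    Compartment.BACKGROUND: (0, 0, 0),
    Compartment.CYTOSOL: (40, 40, 40),
    Compartment.MATRIX: (70, 110, 180),
    Compartment.IBM: (230, 170, 50),
    Compartment.CRISTA: (220, 50, 50),
    Compartment.VESICLE: (170, 70, 220),
}
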