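"""Small classic datasets shipped with the package.

Only desk-scale, public-domain tables live here; everything else the tests
and examples need is generated by :mod:`asymmorph.synthetic`.
"""

from __future__ import annotations

import numpy as np

from .io_landmarks import SquareMatrixInput

__all__ = ["leghorn_correlations", "LEGHORN_VARIABLES"]

LEGHORN_VARIABLES = [
    "skull_length",
    "skull_width",
    "humerus_length",
    "ulna_length",
    "femur_length",
    "tibia_length",
]

_LEGHORN_R = np.array(
    [
        [1.000, 0.584, 0.615, 0.601, 0.570, 0.600],
        [0.584, 1.000, 0.576, 0.530, 0.526, 0.555],
        [0.615, 0.576, 1.000, 0.940, 0.875, 0.878],
        [0.601, 0.530, 0.940, 1.000, 0.877, 0.886],
        [0.570, 0.526, 0.875, 0.877, 1.000, 0.924],
        [0.600, 0.555, 0.878, 0.886, 0.924, 1.000],
    ]
)

# blocks for Wright's decomposition: skull, forelimb (wing), hindlimb (leg)
LEGHORN_BLOCKS = [(0, 1), (2, 3), (4, 5)]


def leghorn_correlations() -> SquareMatrixInput:
    """Sewall Wright's 6×6 correlation matrix of bone measures on 276
    White Leghorn chickens (skull length/width, humerus, ulna, femur,
    tibia) — the classic testbed for the general/special factor model."""
    return SquareMatrixInput(_LEGHORN_R.copy(), list(LEGHORN_VARIABLES), "correlation")
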