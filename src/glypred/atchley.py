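"""Five-factor amino-acid property scores.

Factor 1: polarity / hydrophobicity; Factor 2: secondary-structure
propensity; Factor 3: molecular volume; Factor 4: codon diversity;
Factor 5: electrostatic charge. The padding letter ``O`` scores zero in
every factor (it stands for "no residue").
"""

from __future__ import annotations

import numpy as np

FACTOR_NAMES = (
    "polarity",
    "secondary_structure",
    "molecular_volume",
    "codon_diversity",
    "electrostatic_charge",
)

# (F1, F2, F3, F4, F5) per standard residue.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
    "O": (0.0, 0.0, 0.0, 0.0, 0.0),
}


def factor_matrix(alphabet: str) -> np.ndarray:
    """Return the len(alphabet) x 5 score matrix in alphabet order."""
    return np.array([ATCHLEY_FACTORS[a] for a in alphabet], dtype=float)
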