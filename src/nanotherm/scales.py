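"""Amino-acid alphabets and per-residue descriptor scales.

The one-hot/VHSE channel order is frozen for reproducibility: the 20 standard
amino acids in alphabetical one-letter order, with the alignment gap symbol as
the 21st (last) channel.
"""

from __future__ import annotations

import numpy as np

#: 20 standard amino acids, alphabetical one-letter order.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Alignment gap symbol.
GAP: str = "-"

#: Full 21-symbol alphabet used by aligned sequences (gap last).
ALPHABET: str = AA20 + GAP

#: Number of columns in the fixed-length antibody numbering scheme.
AHO_LENGTH: int = 149

#: index of each symbol in :data:`ALPHABET`
ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

# VHSE: eight principal-component scores per amino acid summarizing
# hydrophobic (VHSE1-2), steric (VHSE3-4) and electronic (VHSE5-8)
# properties (Mei et al., Biopolymers 2005, 80:775-786).
VHSE_TABLE: dict[str, tuple[float, ...]] = {
    "A": (0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48),
    "R": (-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83),
    "N": (-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80),
    "D": (-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56),
    "C": (0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19),
    "Q": (-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41),
    "E": (-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02),
    "G": (-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34),
    "H": (-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65),
    "I": (1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13),
    "L": (1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62),
    "K": (-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13),
    "M": (1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68),
    "F": (1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20),
    "P": (0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56),
    "S": (-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11),
    "T": (-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39),
    "W": (1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85),
    "Y": (0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52),
    "V": (0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03),
}

#: VHSE descriptors per amino acid.
VHSE_DIM: int = 8

# Kyte-Doolittle hydropathy (J Mol Biol 1982, 157:105-132).
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Formal side-chain charge near neutral pH; His carries a small
# conventional partial charge.
CHARGE: dict[str, float] = {aa: 0.0 for aa in AA20}
CHARGE.update({"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0})


def vhse_matrix() -> np.ndarray:
    """20 x 8 VHSE matrix in :data:`AA20` row order."""
    return np.array([VHSE_TABLE[aa] for aa in AA20], dtype=float)


def hydropathy_vector() -> np.ndarray:
    """Length-21 hydropathy lookup in :data:`ALPHABET` order (gap -> 0)."""
    return np.array([HYDROPATHY.get(s, 0.0) for s in ALPHABET], dtype=float)


def charge_vector() -> np.ndarray:
    """Length-21 charge lookup in :data:`ALPHABET` order (gap -> 0)."""
    return np.array([CHARGE.get(s, 0.0) for s in ALPHABET], dtype=float)
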