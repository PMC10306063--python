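"""Amino-acid alphabet constants shared across the package.

The canonical residue-type order everywhere (profile columns, probability
rows, confusion kernels) is the alphabetical one-letter order
``ACDEFGHIKLMNPQRSTVWY``. ``'X'`` denotes an unknown or non-standard
residue (e.g. UNK) and is never a profile column.
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA1)}
N_TYPES = len(AA1)

# one-letter alphabet accepted in target sequences
SEQUENCE_ALPHABET = set(AA1) | {"X"}

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def three_to_one(name: str) -> str:
    """One-letter code for a residue name; 'X' for anything non-standard."""
    return THREE_TO_ONE.get(name.upper().strip(), "X")


def seq_to_indices(seq: str):
    """Integer encoding of a one-letter sequence; 'X' maps to N_TYPES (=20).

    The sentinel index is used to address an all-zero extra column in
    log-odds matrices so that unknown positions contribute nothing.
    """
    import numpy as np

    return np.array([AA_INDEX.get(a, N_TYPES) for a in seq], dtype=np.int64)
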