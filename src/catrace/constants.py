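"""Amino-acid alphabets and background composition.

The 20 standard residues are ordered alphabetically by one-letter code;
every 20-vector of amino-acid probabilities in the package follows this
order. The background composition is the Swiss-Prot release-statistics
amino-acid frequency table, renormalized to sum to one; it is the default
prior for HMM emission probabilities and is configurable everywhere it is
used.
"""

from __future__ import annotations

import numpy as np

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

AA_THREE: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

THREE_TO_ONE: dict[str, str] = {v: k for k, v in AA_THREE.items()}

# Swiss-Prot amino-acid composition (percent), renormalized below.
_SWISSPROT_PCT = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}

AA_BACKGROUND_SWISSPROT: np.ndarray = np.array(
    [_SWISSPROT_PCT[aa] for aa in AA_ALPHABET], dtype=float
)
AA_BACKGROUND_SWISSPROT /= AA_BACKGROUND_SWISSPROT.sum()
AA_BACKGROUND_SWISSPROT.setflags(write=False)

# Atom-type classifier channel layout: CA, C, N, then no-atom.
ATOM_CLASSES: tuple[str, ...] = ("CA", "C", "N", "none")
CA_CHANNEL: int = 0

# Amino-acid classifier channel layout: the 20 standard residues in
# AA_ALPHABET order, then the no/unknown class.
AA_NONE_CHANNEL: int = 20
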