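"""C-alpha-only backbone model container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AA_THREE


@dataclass
class BackboneChain:
    chain_id: str
    residues: list[str]           # one-letter codes, residue 1..T in order
    coords: np.ndarray            # (T, 3) Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.residues) != len(self.coords):
            raise ValueError("residues and coords length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    def resnames3(self) -> list[str]:
        return [AA_THREE.get(r, "UNK") for r in self.residues]


@dataclass
class BackboneModel:
    chains: list[BackboneChain] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def all_coords(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 3))
        return np.vstack([c.coords for c in self.chains])

    def all_residues(self) -> list[str]:
        out: list[str] = []
        for c in self.chains:
            out.extend(c.residues)
        return out
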