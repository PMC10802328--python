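"""C-alpha candidate extraction and redundancy clustering.

The voxel classifier marks several adjacent voxels around each true
C-alpha. Candidates are the voxels whose C-alpha probability strictly
exceeds a threshold (default 0.4); redundant candidates are merged by
single-linkage clustering at a 2 Angstrom radius, each cluster being
represented by its most central member carrying the cluster-averaged
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import AA_ALPHABET, AA_NONE_CHANNEL, CA_CHANNEL


@dataclass
class ProbabilityGrid:
    """Per-voxel class probabilities on a 3D lattice.

    ``values`` has shape (n_classes, nx, ny, nz); voxel (i, j, k) sits at
    Angstrom position ``origin + (i, j, k) * voxel_size``.
    """

    values: np.ndarray
    voxel_size: np.ndarray = field(
        default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (n_classes, nx, ny, nz)")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def same_lattice(self, other: "ProbabilityGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and np.allclose(self.origin, other.origin))


@dataclass
class CaCandidate:
    """One putative C-alpha: position (Angstrom), detection probability,
    and a renormalized 20-vector of amino-acid probabilities."""

    coord: np.ndarray
    p_ca: float
    aa_probs: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        self.aa_probs = np.asarray(self.aa_probs, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("coord must be length-3")
        if self.aa_probs.shape != (20,):
            raise ValueError("aa_probs must be length-20")
        if not 0.0 <= self.p_ca <= 1.0:
            raise ValueError("p_ca must lie in [0, 1]")
        if np.any(self.aa_probs < 0):
            raise ValueError("aa_probs must be non-negative")


@dataclass
class CandidateCluster:
    members: list[CaCandidate]
    representative: CaCandidate


def extract_ca_candidates(
    atom_grid: ProbabilityGrid,
    aa_grid: ProbabilityGrid,
    threshold: float = 0.4,
    ca_channel: int = CA_CHANNEL,
) -> list[CaCandidate]:
    """Voxels with p(CA) strictly above ``threshold``.

    The amino-acid vector at each selected voxel is taken from ``aa_grid``,
    the no/unknown class dropped, and the remaining 20 entries renormalized
    (a voxel whose probability sits entirely on the unknown class yields a
    uniform vector).
    """
    if not atom_grid.same_lattice(aa_grid):
        raise ValueError("atom and amino-acid grids are on different lattices")
    p_ca = atom_grid.values[ca_channel]
    idx = np.argwhere(p_ca > threshold)
    out: list[CaCandidate] = []
    for i, j, k in idx:
        aa = aa_grid.values[:, i, j, k]
        if aa_grid.n_classes == 21:
            aa = np.delete(aa, AA_NONE_CHANNEL)
        s = aa.sum()
        aa = aa / s if s > 0 else np.full(20, 1 / 20)
        coord = atom_grid.origin + np.array([i, j, k]) * atom_grid.voxel_size
        out.append(CaCandidate(coord=coord, p_ca=float(p_ca[i, j, k]),
                               aa_probs=aa))
    return out


def cluster_candidates(
    candidates: list[CaCandidate], radius: float = 2.0
) -> list[CandidateCluster]:
    """Single-linkage clusters under a pairwise distance <= radius rule.

    The representative is the member closest to the member-coordinate
    centroid (ties: lexicographically lowest coordinate); it keeps its own
    lattice position but carries the cluster-averaged probabilities.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not candidates:
        return []
    coords = np.array([c.coord for c in candidates])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(candidates)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)

    clusters: list[CandidateCluster] = []
    for comp in range(n_comp):
        member_idx = np.flatnonzero(labels == comp)
        members = [candidates[i] for i in member_idx]
        pts = coords[member_idx]
        centroid = pts.mean(axis=0)
        d2 = ((pts - centroid) ** 2).sum(axis=1)
        best = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.round(d2, 12)))[0]
        rep_src = members[best]
        rep = CaCandidate(
            coord=rep_src.coord.copy(),
            p_ca=float(np.mean([m.p_ca for m in members])),
            aa_probs=np.mean([m.aa_probs for m in members], axis=0),
        )
        clusters.append(CandidateCluster(members=members, representative=rep))
    # Deterministic output order regardless of input permutation.
    clusters.sort(key=lambda cl: tuple(cl.representative.coord))
    return clusters


_TABLE_COLUMNS = ["x", "y", "z", "p_ca"] + [f"p_{aa}" for aa in AA_ALPHABET]


def write_candidate_table(candidates: list[CaCandidate], path) -> None:
    rows = [
        list(c.coord) + [c.p_ca] + list(c.aa_probs) for c in candidates
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_candidate_table(path) -> list[CaCandidate]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        vals = np.asarray(row, dtype=float)
        out.append(CaCandidate(coord=vals[:3], p_ca=float(np.clip(vals[3], 0, 1)),
                               aa_probs=np.clip(vals[4:24], 0, None)))
    return out
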