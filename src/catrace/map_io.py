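"""Density-map, sequence, and structure I/O plus sub-grid tiling.

Maps are MRC/CCP4 (MRC2014) via gemmi, normalized on read to the canonical
X,Y,Z-ascending axis order; voxel index (i, j, k) corresponds to Angstrom
position ``origin + (i, j, k) * voxel_size``. Densities are min-max
normalized to [0, 1] by default (a constant map normalizes to zeros);
z-score normalization is available. The classifier consumes cubic
sub-grids tiled from the map; per-voxel predictions are stitched back with
averaging on overlaps. Backbone models are written as C-alpha-only PDB
(mmCIF when the atom count exceeds the PDB fixed-width limit).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

from .candidates import ProbabilityGrid
from .model import BackboneChain, BackboneModel
from .constants import THREE_TO_ONE

PDB_ATOM_LIMIT = 99_999


@dataclass
class DensityMap:
    """3D density on an axis-aligned lattice (grid axes = x, y, z)."""

    grid: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")

    def voxel_to_angstrom(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size


def _normalize(grid: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return grid
    if mode == "minmax":
        lo, hi = float(grid.min()), float(grid.max())
        if hi - lo <= 0:
            return np.zeros_like(grid)
        return (grid - lo) / (hi - lo)
    if mode == "zscore":
        sd = float(grid.std())
        if sd == 0:
            return np.zeros_like(grid)
        return (grid - float(grid.mean())) / sd
    raise ValueError(f"unknown normalization '{mode}'")


def read_density_map(path, normalize: str = "minmax") -> DensityMap:
    """Read an MRC/CCP4 map into canonical axis order.

    Axis-permuted files (MAPC/MAPR/MAPS other than 1,2,3) are reordered so
    that the grid's first axis is X. The origin is taken from the ORIGIN
    header words when set, otherwise from NC/NR/NS-START times the voxel
    size.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read density map '{path}': {exc}") from exc
    nstart = [ccp4.header_i32(i) for i in (5, 6, 7)]
    axis_order = [ccp4.header_i32(i) for i in (17, 18, 19)]
    header_origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid, copy=True)
    if np.any(np.isnan(grid)):
        raise IOError(f"map '{path}' has missing voxels after setup")
    cell = ccp4.grid.unit_cell
    if not (np.isclose(cell.alpha, 90) and np.isclose(cell.beta, 90)
            and np.isclose(cell.gamma, 90)):
        warnings.warn("non-orthogonal unit cell; treating axes as Cartesian")
    voxel = np.array(ccp4.grid.spacing)
    if not np.allclose(voxel, voxel[0], rtol=1e-3):
        warnings.warn(f"non-cubic voxels {voxel}")
    if np.any(header_origin != 0):
        origin = header_origin
    else:
        # nstart is stored in file axis order (columns/rows/sections);
        # map it back onto x,y,z.
        nstart_xyz = np.empty(3)
        for file_axis, xyz_axis in enumerate(axis_order):
            nstart_xyz[xyz_axis - 1] = nstart[file_axis]
        origin = nstart_xyz * voxel
    return DensityMap(grid=_normalize(grid.astype(np.float32), normalize),
                      voxel_size=voxel, origin=origin)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a map in canonical axis order with an explicit ORIGIN record."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.grid.shape
    vx, vy, vz = dmap.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


@dataclass
class SubgridTile:
    data: np.ndarray
    index_offset: tuple[int, int, int]


def tile_map(dmap: DensityMap, edge: int = 32, stride: int | None = None
             ) -> list[SubgridTile]:
    """Cover the (zero-padded) map with cubic tiles.

    With ``stride == edge`` the tiles partition the padded grid; smaller
    strides produce overlapping tiles for averaged stitching.
    """
    if stride is None:
        stride = edge
    if stride < 1:
        raise ValueError("stride must be >= 1")
    shape = np.array(dmap.grid.shape)
    n_steps = np.maximum(1, -(-(shape - edge) // stride) + 1)
    padded = (n_steps - 1) * stride + edge
    grid = np.zeros(tuple(padded), dtype=np.float32)
    grid[: shape[0], : shape[1], : shape[2]] = dmap.grid
    tiles = []
    for i in range(n_steps[0]):
        for j in range(n_steps[1]):
            for k in range(n_steps[2]):
                off = (i * stride, j * stride, k * stride)
                block = grid[off[0]: off[0] + edge,
                             off[1]: off[1] + edge,
                             off[2]: off[2] + edge]
                tiles.append(SubgridTile(data=block.copy(), index_offset=off))
    return tiles


def stitch_predictions(
    tiles: list[tuple[np.ndarray, tuple[int, int, int]]],
    map_shape: tuple[int, int, int],
    voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> ProbabilityGrid:
    """Reassemble per-tile class probabilities onto the map lattice.

    Overlapping voxels are averaged; padding beyond the map shape is
    discarded. Every map voxel must be covered by at least one tile.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    n_classes = tiles[0][0].shape[0]
    acc_shape = np.array(map_shape)
    for probs, off in tiles:
        acc_shape = np.maximum(acc_shape, np.array(off) + probs.shape[1:])
    acc = np.zeros((n_classes, *acc_shape))
    cnt = np.zeros(acc_shape)
    for probs, off in tiles:
        if probs.shape[0] != n_classes:
            raise ValueError("inconsistent class counts across tiles")
        sl = tuple(slice(o, o + s) for o, s in zip(off, probs.shape[1:]))
        acc[(slice(None),) + sl] += probs
        cnt[sl] += 1
    core = tuple(slice(0, s) for s in map_shape)
    if np.any(cnt[core] == 0):
        raise ValueError("stitch found uncovered voxels (missing tile?)")
    values = acc[(slice(None),) + core] / cnt[core]
    return ProbabilityGrid(values=values, voxel_size=np.asarray(voxel_size),
                           origin=np.asarray(origin))


# ---------------------------------------------------------------------------
# sequences and structures

def read_fasta_chains(path) -> list[tuple[str, str]]:
    """(record id, sequence) per chain; record order defines chain order."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in '{path}'")
    return records


_CHAIN_IDS = list(string.ascii_uppercase) + [
    a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]


def _to_gemmi_structure(model: BackboneModel, name: str = "catrace"
                        ) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    md = gemmi.Model("1")
    for i, chain in enumerate(model.chains):
        cid = chain.chain_id or _CHAIN_IDS[i]
        gchain = gemmi.Chain(cid)
        for n, (res3, xyz) in enumerate(zip(chain.resnames3(), chain.coords),
                                        start=1):
            res = gemmi.Residue()
            res.name = res3
            res.seqid = gemmi.SeqId(n, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*[float(v) for v in xyz])
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            gchain.add_residue(res)
        md.add_chain(gchain)
    st.add_model(md)
    st.setup_entities()
    return st


def write_pdb(model: BackboneModel, path) -> Path:
    """Write a C-alpha-only model; falls back to mmCIF for huge models.

    Returns the path actually written (suffix may change to .cif when the
    model exceeds PDB's fixed-width atom-serial capacity or two-character
    chain ids are required).
    """
    path = Path(path)
    if not all(np.all(np.isfinite(c.coords)) for c in model.chains):
        raise ValueError("model contains non-finite coordinates")
    st = _to_gemmi_structure(model)
    needs_cif = (model.n_residues > PDB_ATOM_LIMIT
                 or len(model.chains) > 26)
    if needs_cif:
        out = path.with_suffix(".cif")
        warnings.warn(f"model too large for PDB; writing mmCIF to {out}")
        st.make_mmcif_document().write_file(str(out))
        return out
    st.write_pdb(str(path))
    return path


def read_ca_model(path) -> BackboneModel:
    """Read the C-alpha trace of a PDB/mmCIF structure."""
    st = gemmi.read_structure(str(path))
    chains = []
    for chain in st[0]:
        residues, coords = [], []
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            residues.append(THREE_TO_ONE.get(res.name, "X"))
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if residues:
            chains.append(BackboneChain(chain_id=chain.name,
                                        residues=residues,
                                        coords=np.array(coords)))
    return BackboneModel(chains=chains)
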