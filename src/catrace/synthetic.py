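"""Synthetic ground-truth backbones, noisy classifier outputs, and density
maps.

Every pipeline stage is testable without external data. The generator
emulates the statistical features the tracing stages rely on - consecutive
C-alpha atoms 3.8047 Angstrom apart, self-avoiding chain geometry,
near-one-hot amino-acid probability vectors with controllable noise,
dropped sites and false positives - not the physics of image formation.

The noise model mirrors the classifier's error modes:

* each true site is dropped with probability ``p_drop``;
* retained sites are jittered by isotropic Gaussian noise (``jitter_sd``);
* amino-acid probabilities are Dirichlet draws with concentration
  ``aa_concentration`` added to the true identity on a uniform base
  (``None`` means exact one-hot);
* ``Poisson(fp_rate * n_residues)`` false positives appear uniformly in
  the backbone bounding box inflated by 5 Angstrom, with uniform
  amino-acid vectors.

Detection probabilities for true sites are drawn high (Beta(20, 2)); false
positives draw from Uniform(0.41, 0.8) so they survive the default 0.4
threshold and genuinely stress the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .candidates import CaCandidate, write_candidate_table
from .constants import AA_ALPHABET
from .map_io import DensityMap, write_density_map, write_pdb
from .model import BackboneChain, BackboneModel

CA_SPACING = 3.8047          # Angstrom, consecutive C-alpha distance
MIN_NONADJACENT = 3.0        # Angstrom, self-avoidance radius
_TURN_BAND = (80.0, 150.0)   # degrees, pseudo-bond angle band


@dataclass(frozen=True)
class NoiseSpec:
    """Error model applied to ground-truth sites. ``aa_concentration=None``
    yields exact one-hot amino-acid vectors."""

    aa_concentration: float | None = None
    p_drop: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.aa_concentration is not None and self.aa_concentration <= 0:
            raise ValueError("aa_concentration must be positive")
        if not 0 <= self.p_drop < 1:
            raise ValueError("p_drop must lie in [0, 1)")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be non-negative")


ZERO_NOISE = NoiseSpec()


@dataclass
class SyntheticProtein:
    chains: list[tuple[str, np.ndarray]]   # (sequence, (n, 3) coords)
    seed: int

    @property
    def n_residues(self) -> int:
        return sum(len(seq) for seq, _ in self.chains)

    def all_coords(self) -> np.ndarray:
        return np.vstack([c for _, c in self.chains])

    def to_backbone_model(self) -> BackboneModel:
        return BackboneModel(chains=[
            BackboneChain(chain_id=chr(ord("A") + i), residues=list(seq),
                          coords=coords)
            for i, (seq, coords) in enumerate(self.chains)
        ])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _walk_chain(n: int, start: np.ndarray, existing: np.ndarray,
                rng: np.random.Generator, max_step_tries: int = 60
                ) -> np.ndarray | None:
    """Self-avoiding walk with fixed bond length and banded turn angles."""
    coords = np.empty((n, 3))
    coords[0] = start
    d0 = _unit(rng.standard_normal(3))
    coords[1] = coords[0] + CA_SPACING * d0
    for i in range(2, n):
        prev_dir = _unit(coords[i - 1] - coords[i - 2])
        placed = False
        for _ in range(max_step_tries):
            # pseudo-bond angle at residue i-1, uniform in the band
            theta = np.radians(rng.uniform(*_TURN_BAND))
            perp = _random_perpendicular(prev_dir, rng)
            # new direction makes angle (pi - theta) with prev_dir
            new_dir = -np.cos(theta) * prev_dir + np.sin(theta) * perp
            cand = coords[i - 1] + CA_SPACING * _unit(new_dir)
            prior = coords[: i - 1]
            ok = np.all(
                np.linalg.norm(prior - cand, axis=1) >= MIN_NONADJACENT)
            if ok and len(existing):
                ok = np.all(
                    np.linalg.norm(existing - cand, axis=1) >= MIN_NONADJACENT)
            if ok:
                coords[i] = cand
                placed = True
                break
        if not placed:
            return None
    return coords


def generate_backbone(
    n_residues: int, n_chains: int = 1, seed: int = 0,
    max_restarts: int = 50,
) -> SyntheticProtein:
    """Seeded self-avoiding random backbone with fixed 3.8047 A steps.

    ``n_residues`` is per chain; chains are started in well-separated
    positions so inter-chain contacts respect the self-avoidance radius.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues per chain")
    if n_chains < 1:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(seed)
    chains: list[tuple[str, np.ndarray]] = []
    placed: list[np.ndarray] = []
    # generous start spacing: chains cannot collide at their anchors
    spread = CA_SPACING * max(4.0, n_residues ** 0.75)
    for c in range(n_chains):
        coords = None
        for _ in range(max_restarts):
            start = rng.uniform(-spread, spread, 3) if n_chains > 1 else np.zeros(3)
            existing = np.vstack(placed) if placed else np.zeros((0, 3))
            if len(existing) and np.any(
                    np.linalg.norm(existing - start, axis=1) < MIN_NONADJACENT):
                continue
            coords = _walk_chain(n_residues, start, existing, rng)
            if coords is not None:
                break
        if coords is None:
            raise RuntimeError(
                f"self-avoiding walk failed for chain {c} after "
                f"{max_restarts} restarts")
        seq = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
        chains.append((seq, coords))
        placed.append(coords)
    return SyntheticProtein(chains=chains, seed=seed)


def simulate_predictions(
    protein: SyntheticProtein, noise: NoiseSpec = ZERO_NOISE, seed: int = 0
) -> list[CaCandidate]:
    """Noisy candidate list emulating clustered classifier output."""
    rng = np.random.default_rng(seed)
    out: list[CaCandidate] = []
    for seq, coords in protein.chains:
        keep = rng.random(len(seq)) >= noise.p_drop
        for i in np.flatnonzero(keep):
            pos = coords[i] + (rng.normal(0, noise.jitter_sd, 3)
                               if noise.jitter_sd > 0 else 0.0)
            aa_idx = AA_ALPHABET.index(seq[i])
            if noise.aa_concentration is None:
                aa = np.zeros(20)
                aa[aa_idx] = 1.0
            else:
                alpha = np.ones(20)
                alpha[aa_idx] += noise.aa_concentration
                aa = rng.dirichlet(alpha)
            p_ca = float(rng.beta(20, 2))
            out.append(CaCandidate(coord=pos, p_ca=p_ca, aa_probs=aa))
    n_fp = rng.poisson(noise.fp_rate * protein.n_residues)
    if n_fp:
        pts = protein.all_coords()
        lo, hi = pts.min(axis=0) - 5.0, pts.max(axis=0) + 5.0
        for _ in range(n_fp):
            pos = rng.uniform(lo, hi)
            out.append(CaCandidate(coord=pos,
                                   p_ca=float(rng.uniform(0.41, 0.8)),
                                   aa_probs=np.full(20, 1 / 20)))
    return out


def simulate_density(
    protein: SyntheticProtein, voxel_size: float = 1.0,
    sigma_blur: float = 1.0, pad: float = 5.0, normalize: bool = True,
) -> DensityMap:
    """Sum of unit-peak isotropic Gaussians at the C-alpha positions."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = protein.all_coords()
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    ax = [lo[d] + voxel_size * np.arange(shape[d]) for d in range(3)]
    grid = np.zeros(shape, dtype=np.float64)
    inv2s2 = 1.0 / (2 * sigma_blur ** 2)
    for p in pts:
        gx = np.exp(-((ax[0] - p[0]) ** 2) * inv2s2)
        gy = np.exp(-((ax[1] - p[1]) ** 2) * inv2s2)
        gz = np.exp(-((ax[2] - p[2]) ** 2) * inv2s2)
        grid += gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    if normalize:
        peak = grid.max()
        if peak > 0:
            grid = grid / peak
    return DensityMap(grid=grid.astype(np.float32),
                      voxel_size=np.full(3, float(voxel_size)), origin=lo)


def write_fixture_set(
    protein: SyntheticProtein, outdir, noise: NoiseSpec = ZERO_NOISE,
    seed: int = 0, voxel_size: float = 1.0,
) -> dict[str, Path]:
    """FASTA + reference PDB + candidate table + MRC map for one protein."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "chains.fasta",
        "reference": outdir / "reference.pdb",
        "candidates": outdir / "candidates.tsv",
        "map": outdir / "density.mrc",
    }
    with open(paths["fasta"], "w") as fh:
        for i, (seq, _) in enumerate(protein.chains):
            fh.write(f">chain_{chr(ord('A') + i)}\n{seq}\n")
    write_pdb(protein.to_backbone_model(), paths["reference"])
    write_candidate_table(
        simulate_predictions(protein, noise, seed), paths["candidates"])
    write_density_map(simulate_density(protein, voxel_size), paths["map"])
    return paths
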