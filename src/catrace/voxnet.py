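"""UNETR-style 3D transformer voxel classifier.

A cubic density sub-grid is split into non-overlapping cubic patches,
linearly embedded, summed with a learnable positional encoding, and passed
through a stack of pre-norm transformer blocks. Feature maps taken from
intermediate blocks (and the raw input, through a residual stem) feed a
U-Net-style decoder of stride-2 deconvolutions and convolutional fuse
blocks; a 1x1x1 convolution head emits per-voxel class logits.

Two heads are used in practice: 4 output channels for backbone-atom typing
(CA, C, N, no-atom) and 21 for amino-acid typing (20 residues plus
no/unknown). With the default configuration the two instantiations have
92,281,604 and 92,281,893 trainable parameters respectively; the counts
differ only in the head (17 parameters per output channel).

The implementation is NumPy throughout: construction is seeded and
deterministic, the forward pass is pure inference. Training at corpus scale
is out of scope for this package.
"""

from __future__ import annotations

import numpy as np

from .candidates import ProbabilityGrid
from .config import ModelConfig
from .nn import (
    DTYPE,
    Conv3d,
    ConvNormAct,
    ConvTranspose3d,
    Dropout,
    InstanceNorm3d,
    LayerNorm,
    Linear,
    Module,
    ResidualBlock,
    TransformerBlock,
    leaky_relu,
    softmax,
)


class _DeconvNormAct(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.deconv = ConvTranspose3d(c_in, c_out, rng)
        self.norm = InstanceNorm3d()

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return leaky_relu(self.norm(self.deconv(x)))


class VoxelClassifier(Module):
    """Transformer encoder + convolutional decoder over a cubic sub-grid."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        patch_dim = c.patch_edge ** 3 * c.in_channels

        # --- encoder ---
        self.patch_embed = Linear(patch_dim, c.embed_dim, rng)
        self.pos_embed = self.register(
            "pos_embed",
            (rng.standard_normal((c.n_patches, c.embed_dim)) * 0.02).astype(DTYPE),
        )
        self.embed_drop = Dropout(c.dropout)
        self.blocks: list[TransformerBlock] = []
        for i in range(c.n_blocks):
            blk = TransformerBlock(c.embed_dim, c.n_heads, c.mlp_dim, rng)
            self.add(f"block{i + 1}", blk)
            self.blocks.append(blk)
        self.final_norm = LayerNorm(c.embed_dim)

        # --- decoder ---
        F = c.base_feature_width
        n_levels = len(c.skip_blocks)  # 4: widths F, 2F, 4F, 8F
        widths = [F * 2 ** i for i in range(n_levels)]  # [16, 32, 64, 128]

        self.stem = ResidualBlock(c.in_channels, F, rng)

        # Progressive deconv chains bringing each transformer skip to its
        # pyramid level: z3 -> 2F (3 ups), z6 -> 4F (2 ups), z9 -> 8F (1 up).
        self.skip_chains: list[list[_DeconvNormAct]] = []
        for i in range(n_levels - 1):
            width = widths[i + 1]
            n_up = n_levels - 1 - i
            chain = []
            c_in = c.embed_dim
            for u in range(n_up):
                mod = _DeconvNormAct(c_in, width, rng)
                self.add(f"skip{c.skip_blocks[i]}_up{u}", mod)
                chain.append(mod)
                c_in = width
            self.skip_chains.append(chain)

        # Up path: deconv, concatenate skip, fuse. Deepest fuse is residual;
        # the rest use a single fuse conv plus per-stage refinement convs.
        self.up_deconvs: list[_DeconvNormAct] = []
        self.fuses: list[Module] = []
        self.refines: list[list[ConvNormAct]] = []
        deep_w = widths[-1]
        self.up_deconvs.append(
            self.add("up0_deconv", _DeconvNormAct(c.embed_dim, deep_w, rng)))
        self.fuses.append(
            self.add("up0_fuse", ResidualBlock(2 * deep_w, deep_w, rng)))
        self.refines.append([])
        for s, w in enumerate(reversed(widths[:-1])):  # 64, 32, 16
            self.up_deconvs.append(
                self.add(f"up{s + 1}_deconv", _DeconvNormAct(2 * w, w, rng)))
            self.fuses.append(
                self.add(f"up{s + 1}_fuse", ConvNormAct(2 * w, w, 3, rng)))
            refine = []
            for r in range(c.decoder_refine[s]):
                refine.append(self.add(
                    f"up{s + 1}_refine{r}", ConvNormAct(w, w, 3, rng)))
            self.refines.append(refine)

        self.head = Conv3d(F, c.out_channels, 1, rng, bias=True)

    # ------------------------------------------------------------------
    def _patchify(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        g = c.input_edge // c.patch_edge
        p = c.patch_edge
        x = x.reshape(g, p, g, p, g, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(g ** 3, p ** 3)
        return x

    def _to_grid(self, z: np.ndarray) -> np.ndarray:
        g = self.config.input_edge // self.config.patch_edge
        return z.reshape(g, g, g, -1).transpose(3, 0, 1, 2)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Map a (edge, edge, edge) density block to (C, edge, edge, edge) logits."""
        c = self.config
        x = np.asarray(x, dtype=DTYPE)
        if x.shape != (c.input_edge,) * 3:
            raise ValueError(f"expected {(c.input_edge,) * 3} input, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("density sub-grid contains non-finite values")

        tokens = self.embed_drop(self.patch_embed(self._patchify(x)) + self.pos_embed)
        skips = {}
        z = tokens
        for i, blk in enumerate(self.blocks, start=1):
            z = blk(z)
            if i in c.skip_blocks:
                skips[i] = z
        skips[c.skip_blocks[-1]] = self.final_norm(z)

        # decoder
        d = self.up_deconvs[0](self._to_grid(skips[c.skip_blocks[-1]]))
        chain_out = []
        for i, chain in enumerate(self.skip_chains):
            s = self._to_grid(skips[c.skip_blocks[i]])
            for mod in chain:
                s = mod(s)
            chain_out.append(s)
        # deepest: fuse with processed z9-chain
        d = self.fuses[0](np.concatenate([d, chain_out[-1]], axis=0))
        for s in range(1, len(self.fuses)):
            d = self.up_deconvs[s](d)
            skip = chain_out[-1 - s] if s < len(self.fuses) - 1 else self.stem(
                x[None])
            d = self.fuses[s](np.concatenate([d, skip], axis=0))
            for mod in self.refines[s]:
                d = mod(d)
        return self.head(d)


def build_voxel_classifier(config: ModelConfig, seed: int = 0) -> VoxelClassifier:
    """Instantiate the classifier with seeded random weights."""
    return VoxelClassifier(config, seed=seed)


def count_parameters(classifier: VoxelClassifier) -> int:
    """Total trainable scalar parameters (exact, seed-independent)."""
    return classifier.n_parameters()


def predict_subgrid(
    classifier: VoxelClassifier,
    subgrid: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> ProbabilityGrid:
    """Per-voxel class probabilities (softmax over the channel axis)."""
    logits = classifier(np.asarray(subgrid))
    probs = softmax(logits.astype(np.float64), axis=0)
    return ProbabilityGrid(values=probs, voxel_size=np.asarray(voxel_size, float),
                           origin=np.asarray(origin, float))
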