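"""Configuration objects for the voxel classifier and the tracing pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import AA_BACKGROUND_SWISSPROT


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the 3D transformer voxel classifier.

    The encoder is a ViT-Base transformer over non-overlapping ``patch_edge``
    cubic patches of a ``input_edge`` cubic density sub-grid. Features from
    the blocks listed in ``skip_blocks`` (1-based) and the raw input feed a
    U-Net-style convolution/deconvolution decoder whose channel width starts
    at ``base_feature_width`` at full resolution and doubles per level.

    The decoder schedule is recorded explicitly so alternatives remain
    testable:

    * the stem on the raw input is a residual block (two 3x3x3 convolutions
      plus a 1x1x1 shortcut, ``in_channels -> base_feature_width``);
    * each transformer skip is brought to its target resolution by a chain
      of stride-2 deconvolutions (no interleaved convolutions);
    * each decoder stage upsamples by a stride-2 deconvolution, concatenates
      its skip, and fuses with convolutions: the deepest stage uses a
      residual fuse block, the remaining stages a single 3x3x3 convolution
      followed by ``decoder_refine`` extra 3x3x3 convolutions.

    Decoder convolutions carry no bias (each is followed by instance
    normalization, which is non-affine) and use LeakyReLU activations; the
    final 1x1x1 classification head has a bias.
    """

    input_edge: int = 32
    in_channels: int = 1
    patch_edge: int = 16
    embed_dim: int = 768
    n_blocks: int = 12
    skip_blocks: tuple[int, ...] = (3, 6, 9, 12)
    n_heads: int = 12
    mlp_dim: int = 3072
    base_feature_width: int = 16
    out_channels: int = 4
    dropout: float = 0.1
    # Extra 3x3x3 fuse convolutions per decoder stage, deepest -> shallowest,
    # for the stages below the residual deepest stage.
    decoder_refine: tuple[int, ...] = (1, 0, 1)

    def __post_init__(self) -> None:
        if self.input_edge % self.patch_edge != 0:
            raise ValueError(
                f"input_edge {self.input_edge} not divisible by "
                f"patch_edge {self.patch_edge}"
            )
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.out_channels < 2:
            raise ValueError("out_channels must be at least 2")

    @property
    def n_patches(self) -> int:
        return (self.input_edge // self.patch_edge) ** 3

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["skip_blocks"] = tuple(raw["skip_blocks"])
        raw["decoder_refine"] = tuple(raw["decoder_refine"])
        return cls(**raw)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters, recorded for provenance only.

    The package does not run full-scale training; these are the settings a
    training loop would use (NADAM, LR 1e-4 with a 0.1 decay after five
    stagnant epochs, batches of 32-cubed sub-grids).
    """

    optimizer: str = "nadam"
    learning_rate: float = 1e-4
    batch_size: int = 720
    lr_decay_factor: float = 0.1
    lr_patience_epochs: int = 5


@dataclass
class PipelineConfig:
    """End-to-end tracing parameters.

    ``ca_threshold`` is the strict lower bound on the predicted C-alpha
    probability for a voxel to become a hidden-state candidate;
    ``cluster_radius`` (Angstrom) merges redundant candidate voxels;
    ``mu``/``sigma``/``lambda_scale`` parameterize the Gaussian transition
    density over inter-state distances; ``background`` is the amino-acid
    prior entering the emission probabilities.
    """

    ca_threshold: float = 0.4
    cluster_radius: float = 2.0
    mu: float = 3.8047
    sigma: float = 0.036
    lambda_scale: float = 10.0
    background: np.ndarray = field(
        default_factory=lambda: AA_BACKGROUND_SWISSPROT.copy()
    )
    chain_order: str = "input"  # or "longest_first"
    tile_stride: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ca_threshold < 1.0:
            raise ValueError("ca_threshold must lie in (0, 1)")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.chain_order not in ("input", "longest_first"):
            raise ValueError("chain_order must be 'input' or 'longest_first'")

    def summary_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "background"}
        d["background"] = [round(float(x), 6) for x in self.background]
        return d
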