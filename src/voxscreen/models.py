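"""Model contracts for pose rescoring and binder classification.

The pose rescorer is an 11-way classifier over fnat intervals — a dedicated
bin for fnat = 0 plus ten width-0.1 intervals over (0, 1] — whose
probability vector is decoded to a predicted fnat by expectation over bin
representatives (zero bin -> 0.0, interval bins -> midpoints 0.05..0.95 by
default).  The binder classifier emits a binding probability for a single
pose; pairing-level scores average an ensemble of such classifiers.

Checkpoints embed the architecture, grid spec, channel map and binning so
that inference refuses mismatched featurization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .errors import ConfigurationError, InputError
from .gridding import ChannelMap, GridSpec, VoxelGrid

__all__ = [
    "FnatBinning",
    "fnat_bin_index",
    "decode_fnat",
    "ReOutput",
    "VsOutput",
    "ArchitectureConfig",
    "VoxNet",
    "build_model",
    "forward_re",
    "forward_vs",
    "ensemble_score",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class FnatBinning:
    """The 11-bin fnat discretisation with decoding representatives."""

    n_bins: int = 11
    representatives: Tuple[float, ...] = (
        0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95,
    )

    def __post_init__(self):
        if len(self.representatives) != self.n_bins:
            raise ConfigurationError("representatives must have one entry per bin")
        if self.representatives[0] != 0.0:
            raise ConfigurationError("zero bin representative must be 0.0")
        if not all(np.diff(self.representatives) > 0):
            raise ConfigurationError("representatives must be strictly increasing")

    @property
    def edges(self) -> np.ndarray:
        """Upper edges of the 10 interval bins: 0.1, 0.2, ..., 1.0."""
        return np.linspace(0.1, 1.0, self.n_bins - 1)


def fnat_bin_index(fnat: float, binning: FnatBinning = FnatBinning()) -> int:
    """Bin id of an fnat value: 0 iff fnat == 0, else the (0.1(k-1), 0.1k] bin.

    Upper-inclusive interval assignment keeps fnat = 1.0 representable and
    reserves bin 0 strictly for zero-contact poses.
    """
    if not (0.0 <= fnat <= 1.0):
        raise InputError(f"fnat must lie in [0,1], got {fnat}")
    if fnat == 0.0:
        return 0
    k = int(np.searchsorted(binning.edges, fnat, side="left"))
    return min(k, binning.n_bins - 2) + 1


def decode_fnat(probs: np.ndarray, binning: FnatBinning = FnatBinning()) -> float:
    """Expected fnat under the bin distribution (weighted averaging)."""
    probs = np.asarray(probs, float)
    if probs.shape != (binning.n_bins,):
        raise InputError(f"probs must be a {binning.n_bins}-vector")
    if np.any(probs < -1e-12):
        raise InputError("probs must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise InputError(f"probs sum to {probs.sum():.8f}, not 1")
    return float(probs @ np.asarray(binning.representatives))


@dataclass(frozen=True)
class ReOutput:
    """Rescorer output: bin distribution plus its decoded fnat prediction."""

    probs: np.ndarray
    predicted_fnat: float


@dataclass(frozen=True)
class VsOutput:
    """Binder-classifier output: binding probability in [0, 1]."""

    score: float


# ---------------------------------------------------------------------------
# Architectures

HEAD_RE = "re_11bin"
HEAD_VS = "vs_binary"

#: named conv stacks: (c_out, kernel, stride) per block.  arch_a / arch_b are
#: two small stacks of different depth/width used for ensembling; tiny_test
#: trains on a CPU in minutes at reduced grid specs.
_ARCH_BLOCKS: Dict[str, List[Tuple[int, int, int]]] = {
    "tiny_test": [(8, 3, 2), (16, 3, 2)],
    "arch_a": [(16, 3, 2), (32, 3, 2), (64, 3, 2)],
    "arch_b": [(16, 3, 2), (32, 3, 1), (32, 3, 2), (64, 3, 2)],
}


@dataclass(frozen=True)
class ArchitectureConfig:
    name: str
    head: str
    head_width: int = 32

    def __post_init__(self):
        if self.name not in _ARCH_BLOCKS:
            raise ConfigurationError(
                f"unknown architecture {self.name!r}; choose from {sorted(_ARCH_BLOCKS)}"
            )
        if self.head not in (HEAD_RE, HEAD_VS):
            raise ConfigurationError(f"unknown head {self.head!r}")

    @property
    def blocks(self) -> List[Tuple[int, int, int]]:
        return list(_ARCH_BLOCKS[self.name])


class VoxNet:
    """A conv stack over voxel grids with a task head, plus the featurization
    metadata it was built for."""

    def __init__(
        self,
        config: ArchitectureConfig,
        grid_spec: GridSpec,
        channels: ChannelMap,
        binning: FnatBinning = FnatBinning(),
        rng: Optional[np.random.Generator] = None,
    ):
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        self.grid_spec = grid_spec
        self.channels = channels
        self.binning = binning
        layers: List[nn.Layer] = []
        c_in = channels.n_channels
        for c_out, kernel, stride in config.blocks:
            layers.append(nn.Conv3d(c_in, c_out, kernel, stride, rng=rng))
            layers.append(nn.ReLU())
            c_in = c_out
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(c_in, config.head_width, rng=rng))
        layers.append(nn.ReLU())
        n_out = binning.n_bins if config.head == HEAD_RE else 1
        layers.append(nn.Dense(config.head_width, n_out, rng=rng))
        self.net = nn.Sequential(layers)

    # -- inference --------------------------------------------------------

    def _check_grid(self, values: np.ndarray, spec: Optional[GridSpec]) -> None:
        side = self.grid_spec.side_voxels
        expect = (self.channels.n_channels, side, side, side)
        if values.shape[-4:] != expect:
            raise InputError(
                f"grid shape {values.shape} incompatible with model input {expect}"
            )
        if spec is not None and spec != self.grid_spec:
            raise InputError(
                f"grid spec {spec} does not match model spec {self.grid_spec}"
            )

    def logits(self, values: np.ndarray, train: bool = False) -> np.ndarray:
        if values.ndim == 4:
            values = values[None]
        self._check_grid(values, None)
        return self.net.forward(values.astype(np.float32), train=train)


def build_model(
    arch: str,
    head: str,
    grid_spec: GridSpec,
    channels: Optional[ChannelMap] = None,
    binning: FnatBinning = FnatBinning(),
    rng: Optional[np.random.Generator] = None,
) -> VoxNet:
    channels = channels or ChannelMap.default()
    return VoxNet(ArchitectureConfig(name=arch, head=head), grid_spec, channels, binning, rng)


def _grid_values(grid: Union[VoxelGrid, np.ndarray]) -> Tuple[np.ndarray, Optional[GridSpec]]:
    if isinstance(grid, VoxelGrid):
        return grid.values, grid.spec
    return np.asarray(grid), None


def forward_re(grid: Union[VoxelGrid, np.ndarray], model: VoxNet) -> ReOutput:
    """Apply a rescorer to one grid: normalized bin distribution and its
    decoded fnat prediction.  Deterministic given weights and input."""
    if model.config.head != HEAD_RE:
        raise InputError("model does not carry the fnat-bin head")
    values, spec = _grid_values(grid)
    model._check_grid(values, spec)
    probs = nn.softmax(model.logits(values))[0]
    return ReOutput(probs=probs, predicted_fnat=decode_fnat(probs, model.binning))


def forward_vs(grid: Union[VoxelGrid, np.ndarray], model: VoxNet) -> VsOutput:
    """Apply a binder classifier to one grid."""
    if model.config.head != HEAD_VS:
        raise InputError("model does not carry the binary head")
    values, spec = _grid_values(grid)
    model._check_grid(values, spec)
    return VsOutput(score=float(nn.sigmoid(model.logits(values))[0, 0]))


def batch_pred_fnat(model: VoxNet, grids: np.ndarray) -> np.ndarray:
    """Decoded fnat predictions for a (N, C, S, S, S) grid batch."""
    if model.config.head != HEAD_RE:
        raise InputError("model does not carry the fnat-bin head")
    model._check_grid(grids, None)
    probs = nn.softmax(model.logits(grids))
    return probs @ np.asarray(model.binning.representatives)


def batch_vs_scores(model: VoxNet, grids: np.ndarray) -> np.ndarray:
    """Binder probabilities for a (N, C, S, S, S) grid batch."""
    if model.config.head != HEAD_VS:
        raise InputError("model does not carry the binary head")
    model._check_grid(grids, None)
    return nn.sigmoid(model.logits(grids))[:, 0]


def ensemble_score(member_scores: Sequence[float]) -> float:
    """Arithmetic mean of ensemble member scores."""
    if len(member_scores) == 0:
        raise InputError("ensemble_score needs at least one member")
    return float(np.mean(member_scores))


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: VoxNet, path) -> None:
    """Single-file .npz checkpoint embedding weights and featurization metadata."""
    meta = {
        "arch": model.config.name,
        "head": model.config.head,
        "head_width": model.config.head_width,
        "grid_spec": model.grid_spec.to_dict(),
        "channel_map": json.loads(model.channels.to_json()),
        "binning": {
            "n_bins": model.binning.n_bins,
            "representatives": list(model.binning.representatives),
        },
    }
    state = model.net.state_dict()
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state)


def load_checkpoint(path) -> VoxNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    binning = FnatBinning(
        n_bins=int(meta["binning"]["n_bins"]),
        representatives=tuple(meta["binning"]["representatives"]),
    )
    model = VoxNet(
        ArchitectureConfig(meta["arch"], meta["head"], int(meta["head_width"])),
        GridSpec.from_dict(meta["grid_spec"]),
        ChannelMap(rules=tuple((p, e, int(c)) for p, e, c in meta["channel_map"]["rules"])),
        binning,
    )
    model.net.load_state_dict(state)
    return model
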