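"""Nested-skip attention encoder-decoder with deep supervision.

The network follows the UNet++ wiring: a grid of nodes ``X[i][j]`` where
``i`` indexes the resolution level (downsampled by ``2**i``) and ``j`` the
position along the skip pathway.  Each decoder node concatenates all previous
nodes of its level with the transposed-convolution upsampling of the node one
level below, passes the fusion through a conv block and a channel-then-spatial
attention gate, and every full-resolution decoder node ``X[0][j>=1]`` feeds a
1x1-conv + sigmoid supervision head.  The final probability map is the
arithmetic mean of the heads.

The original design uses a pretrained EfficientNet encoder; here the encoder
column is a stack of plain conv blocks ("tiny" backbone) with the identical
nested decoder, which keeps the topology while staying trainable on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, no_grad

__all__ = [
    "ModelConfig",
    "NetworkOutput",
    "SegmentationNetwork",
    "build_model",
    "predict",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    backbone: str = "tiny"
    levels: int = 5
    base_channels: int = 8
    deep_supervision: bool = True
    attention: bool = True
    convs_per_block: int = 1
    input_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        stride = 2 ** (self.levels - 1)
        h, w = self.input_size
        if h % stride or w % stride:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2**(levels-1) = {stride}"
            )
        if self.backbone == "efficient_pretrained":
            raise NotImplementedError(
                "the pretrained EfficientNet encoder requires a deep-learning "
                "framework and a weight download; use backbone='tiny'"
            )
        if self.backbone != "tiny":
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class NetworkOutput:
    """Fused probability map plus the per-head maps it averages."""

    fused: np.ndarray            # (B, H, W) in [0, 1]
    heads: list[np.ndarray] = field(default_factory=list)


class SegmentationNetwork(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        L = config.levels
        ch = [config.base_channels * 2 ** i for i in range(L)]
        self._levels = L

        # grid of node bodies: node (i, j) exists for i + j <= L - 1
        for i in range(L):
            cin = 3 if i == 0 else ch[i - 1]
            setattr(self, f"enc{i}", nn.ConvBlock(cin, ch[i], rng, config.convs_per_block, dtype))
        for j in range(1, L):
            for i in range(L - j):
                setattr(self, f"up{i}_{j}", nn.ConvTranspose2d(ch[i + 1], ch[i], rng, dtype))
                fused_in = ch[i] * (j + 1)  # j same-level nodes + upsampled map
                setattr(self, f"node{i}_{j}", nn.ConvBlock(fused_in, ch[i], rng, config.convs_per_block, dtype))
                if config.attention:
                    setattr(self, f"att{i}_{j}", nn.ChannelSpatialAttention(ch[i], rng, dtype=dtype))
        n_heads = (L - 1) if config.deep_supervision else 1
        for k in range(n_heads):
            setattr(self, f"head{k}", nn.Conv2d(ch[0], 1, 1, rng, dtype))

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        cfg = self.config
        L = self._levels
        h, w = x.shape[2], x.shape[3]
        stride = 2 ** (L - 1)
        if x.shape[1] != 3:
            raise ValueError(f"expected 3-channel input, got {x.shape[1]} channels")
        if h % stride or w % stride:
            raise ValueError(f"input {h}x{w} not divisible by network stride {stride}")

        grid: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(L):
            if i > 0:
                cur = F.maxpool2x2(cur)
            cur = getattr(self, f"enc{i}")(cur)
            grid[(i, 0)] = cur
        for j in range(1, L):
            for i in range(L - 1 - j, -1, -1):
                up = getattr(self, f"up{i}_{j}")(grid[(i + 1, j - 1)])
                cat = F.concat([grid[(i, jj)] for jj in range(j)] + [up], axis=1)
                out = getattr(self, f"node{i}_{j}")(cat)
                if cfg.attention:
                    out = getattr(self, f"att{i}_{j}")(out)
                grid[(i, j)] = out

        if cfg.deep_supervision:
            top_nodes = [grid[(0, j)] for j in range(1, L)]
        else:
            top_nodes = [grid[(0, L - 1)]]
        heads = []
        for k, node in enumerate(top_nodes):
            logits = getattr(self, f"head{k}")(node)          # (B,1,H,W)
            heads.append(F.reshape(F.sigmoid(logits), (x.shape[0], h, w)))
        if len(heads) == 1:
            fused = heads[0]
        else:
            acc = heads[0]
            for hmap in heads[1:]:
                acc = acc + hmap
            fused = acc * (1.0 / len(heads))
        return fused, heads

    __call__ = forward


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNetwork:
    """Construct the network with reproducible (seeded) initialisation."""
    return SegmentationNetwork(config, seed=seed)


def _as_batch(batch: np.ndarray, dtype) -> Tensor:
    arr = np.asarray(batch, dtype=dtype)
    if arr.ndim == 3:  # single H,W,3 image
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("batch must be (B,H,W,3) or (H,W,3)")
    if arr.shape[-1] == 3:
        arr = arr.transpose(0, 3, 1, 2)
    elif arr.shape[1] != 3:
        raise ValueError(f"cannot locate a 3-channel axis in shape {arr.shape}")
    return Tensor(np.ascontiguousarray(arr))


def predict(net: SegmentationNetwork, batch: np.ndarray) -> NetworkOutput:
    """Deterministic inference returning fused and per-head probability maps."""
    x = _as_batch(batch, net.dtype)
    with no_grad():
        fused, heads = net(x)
    return NetworkOutput(fused=fused.data, heads=[h.data for h in heads])


def count_parameters(net: nn.Module) -> int:
    return int(sum(p.data.size for p in net.parameters()))


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path, student: SegmentationNetwork, teacher_state=None, extra: dict | None = None) -> None:
    """Serialise student (and optional teacher EMA shadow) with the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"student/{k}": v for k, v in student.state_dict().items()}
    meta = {"config": asdict(student.config), "extra": extra or {}}
    if teacher_state is not None:
        arrays.update({f"teacher/{k}": v for k, v in teacher_state.shadow_params.items()})
        meta["teacher"] = {"alpha": teacher_state.alpha, "step": teacher_state.step}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Return (student_net, teacher_state_or_None, meta dict)."""
    from .teacher import TeacherState

    try:
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(bytes(data["__meta__"]).decode())
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable or corrupt checkpoint: {path} ({exc})") from exc
    cfg = meta["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    net = SegmentationNetwork(ModelConfig(**cfg))
    net.load_state_dict({k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("student/")})
    teacher = None
    if "teacher" in meta:
        shadow = {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("teacher/")}
        teacher = TeacherState(shadow_params=shadow, alpha=meta["teacher"]["alpha"],
                               step=meta["teacher"]["step"])
    return net, teacher, meta.get("extra", {})
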