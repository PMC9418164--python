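"""Input perturbations for consistency training, with transformation-consistent
alignment.

Three perturbation kinds are supported: random scaling, additive Gaussian
noise, and right-angle rotation.  Rotation is restricted to {90, 180, 270}
degrees so that applying and inverting it is an exact pixel permutation —
arbitrary angles would make the consistency target depend on interpolation.
Scaling resizes the full frame to a stride-compatible size (the network is
fully convolutional); its alignment is the inverse resize, exact up to
interpolation.  Noise needs no geometric alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "PerturbationSpec",
    "ConsistencyBundle",
    "KINDS",
    "make_rotation_spec",
    "make_noise_spec",
    "make_scaling_spec",
    "sample_specs",
    "apply_perturbation",
    "align_prediction",
    "build_bundle",
]

KINDS = ("random_scaling", "gaussian_noise", "rotation")
DEFAULT_NOISE_SD = 0.03
SCALING_RANGE = (0.8, 1.25)


@dataclass
class PerturbationSpec:
    kind: str
    params: dict
    seed: int = 0


@dataclass
class ConsistencyBundle:
    reference: np.ndarray
    aligned: list = field(default_factory=list)
    specs: list = field(default_factory=list)


# -- spec factories ----------------------------------------------------------

def make_rotation_spec(angle: int, seed: int = 0) -> PerturbationSpec:
    if angle not in (90, 180, 270):
        raise ValueError(f"rotation angle must be one of 90/180/270, got {angle}")
    return PerturbationSpec("rotation", {"angle": int(angle)}, seed)


def make_noise_spec(sd: float = DEFAULT_NOISE_SD, seed: int = 0) -> PerturbationSpec:
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    return PerturbationSpec("gaussian_noise", {"sd": float(sd)}, seed)


def make_scaling_spec(factor: float, input_size: tuple[int, int],
                      size_multiple: int = 8, seed: int = 0) -> PerturbationSpec:
    lo, hi = SCALING_RANGE
    if not lo <= factor <= hi:
        raise ValueError(f"scaling factor must be in [{lo}, {hi}], got {factor}")
    h, w = input_size
    sh = max(size_multiple, int(round(factor * h / size_multiple)) * size_multiple)
    sw = max(size_multiple, int(round(factor * w / size_multiple)) * size_multiple)
    return PerturbationSpec(
        "random_scaling",
        {"factor": float(factor), "input_size": (int(h), int(w)),
         "scaled_size": (sh, sw)},
        seed,
    )


def sample_specs(kinds, input_size, rng: np.random.Generator, *,
                 noise_sd: float = DEFAULT_NOISE_SD, size_multiple: int = 8):
    """One seeded spec per requested kind (the per-step perturbation draw)."""
    specs = []
    for kind in kinds:
        seed = int(rng.integers(2 ** 31))
        if kind == "rotation":
            angle = int(rng.choice((90, 180, 270)))
            specs.append(make_rotation_spec(angle, seed))
        elif kind == "gaussian_noise":
            specs.append(make_noise_spec(noise_sd, seed))
        elif kind == "random_scaling":
            factor = float(rng.uniform(*SCALING_RANGE))
            specs.append(make_scaling_spec(factor, input_size, size_multiple, seed))
        else:
            raise ValueError(f"unknown perturbation kind {kind!r}")
    return specs


# -- resize helpers ----------------------------------------------------------

def _resize_first_axes(arr: np.ndarray, ah: np.ndarray, aw: np.ndarray) -> np.ndarray:
    """Linear resize of the two leading (spatial) axes of a 2D/3D array."""
    if arr.ndim == 2:
        return ah @ arr @ aw.T
    return np.einsum("oh,hwc,pw->opc", ah, arr, aw, optimize=True)


def _scaling_matrices(spec: PerturbationSpec, inverse: bool = False):
    p = spec.params
    if "input_size" not in p or "scaled_size" not in p:
        raise ValueError("scaling spec lacks size information; not invertible")
    (h, w), (sh, sw) = p["input_size"], p["scaled_size"]
    if inverse:
        return F.linear_resize_matrix(h, sh), F.linear_resize_matrix(w, sw)
    return F.linear_resize_matrix(sh, h), F.linear_resize_matrix(sw, w)


# -- apply / align on numpy arrays (H,W[,C]) --------------------------------

def apply_perturbation(image: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if spec.kind == "rotation":
        k = spec.params["angle"] // 90
        return np.ascontiguousarray(np.rot90(image, k, axes=(0, 1)))
    if spec.kind == "gaussian_noise":
        sd = spec.params["sd"]
        if sd == 0:
            return image.copy()
        noise = np.random.default_rng(spec.seed).normal(0.0, sd, image.shape)
        return np.clip(image + noise, 0.0, 1.0)
    if spec.kind == "random_scaling":
        ah, aw = _scaling_matrices(spec)
        return _resize_first_axes(image, ah, aw)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


def align_prediction(pred: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Map a prediction made on the perturbed input back to the reference frame."""
    pred = np.asarray(pred, dtype=np.float64)
    if spec.kind == "rotation":
        k = spec.params["angle"] // 90
        return np.ascontiguousarray(np.rot90(pred, -k, axes=(0, 1)))
    if spec.kind == "gaussian_noise":
        return pred
    if spec.kind == "random_scaling":
        ah, aw = _scaling_matrices(spec, inverse=True)
        return _resize_first_axes(pred, ah, aw)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


# -- batch (B,C,H,W) / tensor variants used by the trainer -------------------

def apply_batch(batch: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Apply a spec to a (B,C,H,W) image batch (numpy, no gradients)."""
    if spec.kind == "rotation":
        k = spec.params["angle"] // 90
        return np.ascontiguousarray(np.rot90(batch, k, axes=(-2, -1)))
    if spec.kind == "gaussian_noise":
        sd = spec.params["sd"]
        if sd == 0:
            return batch.copy()
        noise = np.random.default_rng(spec.seed).normal(0.0, sd, batch.shape)
        return np.clip(batch + noise, 0.0, 1.0).astype(batch.dtype)
    if spec.kind == "random_scaling":
        ah, aw = _scaling_matrices(spec)
        ah = ah.astype(batch.dtype)
        aw = aw.astype(batch.dtype)
        return np.matmul(np.matmul(ah, batch), aw.T)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


def align_tensor(pred: Tensor, spec: PerturbationSpec) -> Tensor:
    """Differentiable alignment of a (B,H,W) prediction tensor."""
    if spec.kind == "rotation":
        return F.rot90(pred, -(spec.params["angle"] // 90))
    if spec.kind == "gaussian_noise":
        return pred
    if spec.kind == "random_scaling":
        ah, aw = _scaling_matrices(spec, inverse=True)
        return F.resize_linear(pred, ah, aw)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


# -- bundles -----------------------------------------------------------------

def _call_net(net, image: np.ndarray) -> np.ndarray:
    """Run either a plain callable stub or a SegmentationNetwork on one image."""
    if hasattr(net, "state_dict"):
        from .model import predict

        return predict(net, image).fused[0]
    return np.asarray(net(image), dtype=np.float64)


def build_bundle(net, image: np.ndarray, specs, reference_net=None) -> ConsistencyBundle:
    """Reference prediction plus aligned predictions on each perturbed input.

    ``reference_net`` defaults to ``net``; in mean-teacher training the
    reference comes from the teacher while the perturbed branches come from
    the student.
    """
    specs = list(specs)
    if not 1 <= len(specs) <= 3:
        raise ValueError(f"need between 1 and 3 perturbation specs, got {len(specs)}")
    kinds = [s.kind for s in specs]
    if len(set(kinds)) != len(kinds):
        raise ValueError("at most one spec per perturbation kind")
    ref_net = net if reference_net is None else reference_net
    reference = _call_net(ref_net, image)
    aligned = [
        align_prediction(_call_net(net, apply_perturbation(image, s)), s) for s in specs
    ]
    return ConsistencyBundle(reference=reference, aligned=aligned, specs=specs)
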