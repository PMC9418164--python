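"""Continuous update of pseudo-labels (CUPL).

At regular epoch intervals the teacher relabels every unlabeled image with a
soft probability map.  Images where teacher and student disagree most (pixel
-mean squared difference of their maps) are deemed unconfident and dropped;
the confident remainder is averaged element-wise with its previous-round
pseudo-label, damping oscillations, and fed into training as soft BCE targets
alongside the labeled set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ImageSample

__all__ = [
    "PseudoLabelRecord",
    "CuplConfig",
    "generate_pseudo_labels",
    "confidence_filter",
    "average_update",
    "to_training_targets",
    "write_pseudo_snapshots",
]


@dataclass
class PseudoLabelRecord:
    id: str
    current: np.ndarray                       # H,W soft label in [0,1]
    previous: np.ndarray | None = None
    disagreement: float = 0.0                 # teacher-student MSE
    accepted: bool = False
    round: int = 0
    sample: ImageSample | None = field(default=None, repr=False)


@dataclass
class CuplConfig:
    update_interval_epochs: int = 10
    keep_fraction: float = 0.8
    warmup_epochs: int = 40
    average_with_previous: bool = True
    binarize_targets: bool = True

    def __post_init__(self):
        if self.update_interval_epochs < 1:
            raise ValueError("update_interval_epochs must be >= 1")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")


def _predict_map(net, image: np.ndarray) -> np.ndarray:
    """Probability map from either a SegmentationNetwork or a callable stub."""
    if hasattr(net, "state_dict"):
        from .model import predict

        return predict(net, image).fused[0]
    return np.asarray(net(image), dtype=np.float64)


def generate_pseudo_labels(teacher_net, student_net, unlabeled: list[ImageSample],
                           previous: dict[str, "PseudoLabelRecord"] | None = None,
                           ) -> list[PseudoLabelRecord]:
    """Teacher soft labels plus per-image teacher-student disagreement.

    ``previous`` (id -> record of the last round) threads the previous-round
    map and round counter into the new records.
    """
    previous = previous or {}
    records = []
    for s in unlabeled:
        t_map = _predict_map(teacher_net, s.image)
        s_map = _predict_map(student_net, s.image)
        if t_map.shape != s_map.shape:
            raise ValueError("teacher and student map shapes differ")
        old = previous.get(s.id)
        records.append(PseudoLabelRecord(
            id=s.id,
            current=np.asarray(t_map, dtype=np.float64),
            previous=None if old is None else old.current,
            disagreement=float(((t_map - s_map) ** 2).mean()),
            round=0 if old is None else old.round,
            sample=s,
        ))
    return records


def confidence_filter(records: list[PseudoLabelRecord], keep_fraction: float,
                      ) -> list[PseudoLabelRecord]:
    """Keep the ceil(keep_fraction * n) lowest-disagreement records.

    Returns all records sorted ascending by (disagreement, id) with the
    ``accepted`` flag set on the kept prefix; ties break lexicographically.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (r.disagreement, r.id))
    n_keep = math.ceil(keep_fraction * len(ordered))
    for i, rec in enumerate(ordered):
        rec.accepted = i < n_keep
    return ordered


def average_update(records: list[PseudoLabelRecord],
                   average_with_previous: bool = True) -> list[PseudoLabelRecord]:
    """Average each record with its previous-round map and advance the round.

    First-round records (no previous map) keep their current map; in every
    case ``previous`` is set to the pre-update current map.
    """
    for rec in records:
        pre = rec.current
        if rec.previous is not None and average_with_previous:
            if rec.previous.shape != rec.current.shape:
                raise ValueError(f"shape mismatch between rounds for {rec.id!r}")
            rec.current = 0.5 * (rec.current + rec.previous)
        rec.previous = pre
        rec.round += 1
    return records


def write_pseudo_snapshots(records: list[PseudoLabelRecord], out_dir,
                           round_idx: int, epoch: int | None = None) -> None:
    """Persist one round's soft labels as 16-bit PNGs plus a CSV index.

    The index (id, round, epoch, disagreement, accepted) is appended across
    rounds, so the evolution of each image's pseudo-label can be inspected.
    """
    import csv
    from pathlib import Path

    import imageio.v3 as iio

    out_dir = Path(out_dir)
    round_dir = out_dir / f"round_{round_idx:03d}"
    round_dir.mkdir(parents=True, exist_ok=True)
    index = out_dir / "index.csv"
    new_file = not index.exists()
    with index.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(["id", "round", "epoch", "disagreement", "accepted"])
        for rec in records:
            soft16 = np.clip(rec.current, 0.0, 1.0) * 65535.0
            iio.imwrite(round_dir / f"{rec.id}.png", soft16.round().astype(np.uint16))
            writer.writerow([rec.id, round_idx, "" if epoch is None else epoch,
                             f"{rec.disagreement:.8g}", int(rec.accepted)])


def to_training_targets(records: list[PseudoLabelRecord], binarize: bool = True
                        ) -> list[tuple[ImageSample, np.ndarray]]:
    """Accepted records as (image sample, mask) training pairs.

    The round-averaging memory stays soft (that is where the confidence
    information lives), but the emitted training target is by default the
    0.5-binarised map — the pseudo ground truth u_i is a binary mask.  Pass
    ``binarize=False`` to train on the soft maps instead.
    """
    out = []
    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.id!r} was not accepted by the confidence filter")
        if rec.sample is None:
            raise ValueError(f"record {rec.id!r} carries no image sample")
        target = (rec.current >= 0.5).astype(np.float32) if binarize else rec.current
        out.append((rec.sample, target))
    return out
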