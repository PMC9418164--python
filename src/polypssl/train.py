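"""Training orchestration for the three regimes.

* ``baseline``   — supervised BCE on the labeled set only.
* ``cl``         — adds the perturbation-consistency loss on unlabeled images:
                   the teacher (EMA of the student) predicts the clean image,
                   the student predicts perturbed versions, predictions are
                   aligned back to the reference frame and penalised by MSE,
                   weighted by a ramped lambda.
* ``cl_cupl``    — additionally regenerates confidence-filtered, round-averaged
                   pseudo-labels every few epochs and trains on them with the
                   combined (labeled + pseudo) loss.

Every stochastic choice (weight init, batch order, perturbation draws) is
derived from ``RunConfig.seed``, so a run is bit-reproducible on a platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cupl import (
    CuplConfig,
    average_update,
    confidence_filter,
    generate_pseudo_labels,
    to_training_targets,
    write_pseudo_snapshots,
)
from .data import DatasetSplit, ImageSample, load_dataset, split_dataset, write_manifest
from .fixtures import FixtureConfig, generate_fixture_set
from .losses import EPS, LossReport, lambda_schedule
from .metrics import EvalResult, evaluate
from .model import ModelConfig, SegmentationNetwork, build_model, predict, save_checkpoint, load_checkpoint
from .nn import functional as F
from .nn.optim import Adam
from .nn.tensor import Tensor
from .perturb import apply_batch, align_tensor, sample_specs
from .teacher import init_teacher, ema_update

__all__ = [
    "DataConfig", "RunConfig", "TrainingResult",
    "train", "evaluate_checkpoint", "run_regime_comparison",
    "fixture_protocol_config", "config_to_yaml", "config_from_yaml",
]

REGIMES = ("baseline", "cl", "cl_cupl")


@dataclass
class DataConfig:
    image_dir: str | None = None
    mask_dir: str | None = None
    fixture: FixtureConfig | None = None


@dataclass
class RunConfig:
    regime: str = "baseline"
    model: ModelConfig = field(default_factory=ModelConfig)
    data: DataConfig = field(default_factory=DataConfig)
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_labeled: int = 50
    n_unlabeled: int | None = None
    epochs: int = 200
    batch_size: int = 40
    lr: float = 1e-5
    lambda_max: float = 1.0
    ramp_epochs: int = 40
    perturbations: tuple[str, ...] = ("random_scaling", "gaussian_noise", "rotation")
    noise_sd: float = 0.03
    cupl: CuplConfig = field(default_factory=CuplConfig)
    seed: int = 0
    split_seed: int | None = None
    alpha: float = 0.999

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.regime == "cl_cupl" and self.cupl is None:
            raise ValueError("regime cl_cupl requires a cupl config")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainingResult:
    loss_history: list[LossReport]
    eval_per_epoch: list[EvalResult]
    best_checkpoint: str | None
    cupl_rounds: int
    seed: int
    split: DatasetSplit
    best_shadow: dict
    best_val_dice: float
    pseudo_records: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


# -- differentiable losses on tensors ----------------------------------------

def bce_tensor(pred: Tensor, target: np.ndarray) -> Tensor:
    """Binary cross-entropy (soft targets allowed), mean over all pixels."""
    t = Tensor(np.asarray(target, dtype=pred.dtype))
    p = F.clip(pred, EPS, 1.0 - EPS)
    one = Tensor(np.asarray(1.0, dtype=pred.dtype))
    return -F.mean(t * F.log(p) + (one - t) * F.log(one - p))


def mse_tensor(a: Tensor, b: np.ndarray) -> Tensor:
    return F.mean(F.square(a - Tensor(np.asarray(b, dtype=a.dtype))))


# -- helpers ------------------------------------------------------------------

def _images_to_batch(samples: list[ImageSample]) -> np.ndarray:
    return np.ascontiguousarray(
        np.stack([s.image for s in samples]).transpose(0, 3, 1, 2).astype(np.float32)
    )


def predict_samples(net: SegmentationNetwork, samples: list[ImageSample],
                    batch_size: int = 16) -> list[np.ndarray]:
    maps: list[np.ndarray] = []
    for i in range(0, len(samples), batch_size):
        out = predict(net, _images_to_batch(samples[i:i + batch_size]))
        maps.extend(out.fused)
    return maps


class _Cycler:
    """Seeded, reshuffled cycling over a list of indices."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n) if n else np.array([], dtype=int)
        self.pos = 0

    def take(self, k: int) -> np.ndarray:
        if self.n == 0:
            return np.array([], dtype=int)
        out = []
        while len(out) < k:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            out.append(self.order[self.pos])
            self.pos += 1
        return np.array(out, dtype=int)


def _resolve_samples(config: RunConfig) -> list[ImageSample]:
    d = config.data
    if d.fixture is not None:
        samples = generate_fixture_set(d.fixture)
        if tuple(d.fixture.image_size) != tuple(config.model.input_size):
            raise ValueError("fixture image_size must match model input_size")
        return samples
    if d.image_dir is None or d.mask_dir is None:
        raise ValueError("data config needs either a fixture spec or image/mask dirs")
    return load_dataset(d.image_dir, d.mask_dir, target_size=config.model.input_size)


# -- main loop ----------------------------------------------------------------

def train(config: RunConfig, workdir=None) -> TrainingResult:
    workdir = Path(workdir) if workdir is not None else None
    samples = _resolve_samples(config)
    split_seed = config.seed if config.split_seed is None else config.split_seed
    split = split_dataset(samples, config.ratios, config.n_labeled, split_seed)
    unlabeled = split.unlabeled
    if config.n_unlabeled is not None:
        if config.n_unlabeled > len(unlabeled):
            raise ValueError(f"n_unlabeled={config.n_unlabeled} exceeds the "
                             f"{len(unlabeled)} available unlabeled samples")
        unlabeled = unlabeled[:config.n_unlabeled]
    labeled = split.labeled
    use_unlabeled = config.regime != "baseline" and len(unlabeled) > 0

    base_ss = np.random.SeedSequence(config.seed)
    ss_model, ss_shuffle, ss_perturb = base_ss.spawn(3)
    model_seed = int(ss_model.generate_state(1)[0] & 0x7FFFFFFF)
    shuffle_rng = np.random.default_rng(ss_shuffle)
    perturb_rng = np.random.default_rng(ss_perturb)

    student = build_model(config.model, seed=model_seed)
    teacher = init_teacher(student, alpha=config.alpha)
    teacher_net = build_model(config.model, seed=model_seed)
    opt = Adam(student.parameters(), lr=config.lr)

    # the labeled sub-batch size is the same in every regime so the supervised
    # gradient stream is comparable; regimes without unlabeled data simply
    # leave the other half of the batch unused
    labeled_bs = max(1, config.batch_size // 2)
    unlabeled_bs = config.batch_size - labeled_bs if use_unlabeled else 0
    steps_per_epoch = math.ceil(len(labeled) / labeled_bs)
    stride = 2 ** (config.model.levels - 1)

    unlab_cycler = _Cycler(len(unlabeled), shuffle_rng) if use_unlabeled else None
    pseudo_targets: list[tuple[ImageSample, np.ndarray]] = []
    pseudo_cycler: _Cycler | None = None
    pseudo_store: dict = {}
    last_records: list = []
    cupl_rounds = 0
    diag = {"bce_ids": set(), "cl_ids": set(), "pseudo_ids": set()}

    history: list[LossReport] = []
    spec_log: list[dict] = []
    eval_per_epoch: list[EvalResult] = []
    best_val_dice = -1.0
    best_shadow: dict = {}
    global_step = 0

    for epoch in range(config.epochs):
        # -- pseudo-label round boundary ------------------------------------
        if (config.regime == "cl_cupl" and use_unlabeled
                and epoch >= config.cupl.warmup_epochs
                and (epoch - config.cupl.warmup_epochs) % config.cupl.update_interval_epochs == 0):
            teacher.apply_to(teacher_net)
            records = generate_pseudo_labels(teacher_net, student, unlabeled,
                                             previous=pseudo_store)
            records = confidence_filter(records, config.cupl.keep_fraction)
            accepted = [r for r in records if r.accepted]
            average_update(accepted, config.cupl.average_with_previous)
            pseudo_store.update({r.id: r for r in accepted})
            pseudo_targets = to_training_targets(accepted, binarize=config.cupl.binarize_targets)
            pseudo_cycler = _Cycler(len(pseudo_targets), shuffle_rng)
            last_records = records
            cupl_rounds += 1
            if workdir is not None:
                write_pseudo_snapshots(records, workdir / "pseudo_labels",
                                       cupl_rounds, epoch=epoch)

        lam = 0.0 if config.regime == "baseline" else lambda_schedule(
            epoch, config.lambda_max, config.ramp_epochs)
        order = shuffle_rng.permutation(len(labeled))

        for step in range(steps_per_epoch):
            idx = order[step * labeled_bs:(step + 1) * labeled_bs]
            batch = [labeled[i] for i in idx]
            diag["bce_ids"].update(s.id for s in batch)
            x = Tensor(_images_to_batch(batch))
            y = np.stack([s.mask for s in batch]).astype(np.float32)

            _, heads = student(x)
            sup = bce_tensor(heads[0], y)
            for hmap in heads[1:]:
                sup = sup + bce_tensor(hmap, y)
            sup = sup * (1.0 / len(heads))
            total = sup

            cl_val = 0.0
            if use_unlabeled:
                uidx = unlab_cycler.take(unlabeled_bs)
                ubatch = [unlabeled[i] for i in uidx]
                diag["cl_ids"].update(s.id for s in ubatch)
                xu = _images_to_batch(ubatch)
                teacher.apply_to(teacher_net)
                ref = predict(teacher_net, xu).fused
                specs = sample_specs(config.perturbations, xu.shape[2:], perturb_rng,
                                     noise_sd=config.noise_sd, size_multiple=stride)
                for spec in specs:  # logged with seeds so a step can be replayed
                    spec_log.append({"step": global_step, "epoch": epoch,
                                     "kind": spec.kind, "seed": spec.seed,
                                     "params": repr(spec.params)})
                cl_t = None
                for spec in specs:
                    xp = apply_batch(xu, spec)
                    pf, _ = student(Tensor(xp))
                    aligned = align_tensor(pf, spec)
                    term = mse_tensor(aligned, ref)
                    cl_t = term if cl_t is None else cl_t + term
                cl_t = cl_t * (1.0 / len(specs))
                cl_val = cl_t.item()
                if lam > 0:
                    total = total + lam * cl_t

            pseudo_val = None
            combined_val = None
            if pseudo_targets:
                pidx = pseudo_cycler.take(labeled_bs)
                pbatch = [pseudo_targets[i] for i in pidx]
                diag["pseudo_ids"].update(s.id for s, _ in pbatch)
                xp_img = Tensor(_images_to_batch([s for s, _ in pbatch]))
                tgt = np.stack([m for _, m in pbatch]).astype(np.float32)
                _, pheads = student(xp_img)
                pterm = bce_tensor(pheads[0], tgt)
                for hmap in pheads[1:]:
                    pterm = pterm + bce_tensor(hmap, tgt)
                pterm = pterm * (1.0 / len(pheads))
                pseudo_val = pterm.item()
                combined_val = sup.item() + pseudo_val
                total = total + pterm

            student.zero_grad()
            total.backward()
            opt.step()
            ema_update(teacher, student)
            history.append(LossReport(
                supervised=sup.item(), consistency=cl_val, lambda_weight=lam,
                overall=sup.item() + lam * cl_val,
                pseudo_term=pseudo_val, combined=combined_val,
                epoch=epoch, step=global_step,
            ))
            global_step += 1

        # -- validation with the teacher -------------------------------------
        teacher.apply_to(teacher_net)
        val_maps = predict_samples(teacher_net, split.val)
        res = evaluate(val_maps, [s.mask for s in split.val])
        eval_per_epoch.append(res)
        if res.dice > best_val_dice:
            best_val_dice = res.dice
            best_shadow = {k: v.copy() for k, v in teacher.shadow_params.items()}

    best_path = None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)
        teacher_best = init_teacher(student, alpha=config.alpha)
        teacher_best.shadow_params = best_shadow
        teacher_best.step = teacher.step
        best_path = str(workdir / "best_checkpoint.npz")
        save_checkpoint(best_path, student, teacher_best,
                        extra={"best_val_dice": best_val_dice, "seed": config.seed})
        pd.DataFrame([asdict(r) for r in history]).to_csv(workdir / "train_log.csv", index=False)
        pd.DataFrame([r.to_dict() for r in eval_per_epoch]).to_csv(
            workdir / "val_metrics.csv", index=False)
        (workdir / "config.yaml").write_text(config_to_yaml(config))
        write_manifest(split, workdir / "manifest.tsv")
        if spec_log:
            pd.DataFrame(spec_log).to_csv(workdir / "perturbations.csv", index=False)

    return TrainingResult(
        loss_history=history, eval_per_epoch=eval_per_epoch,
        best_checkpoint=best_path, cupl_rounds=cupl_rounds, seed=config.seed,
        split=split, best_shadow=best_shadow, best_val_dice=best_val_dice,
        pseudo_records=last_records,
        diagnostics={k: sorted(v) for k, v in diag.items()},
    )


# -- evaluation ---------------------------------------------------------------

def evaluate_checkpoint(checkpoint, image_dir, mask_dir=None, threshold: float = 0.5) -> EvalResult:
    """Load a checkpoint (teacher weights preferred) and score a directory."""
    if mask_dir is None:
        raise ValueError("mask_dir is required to compute metrics")
    net, teacher_state, _ = load_checkpoint(checkpoint)
    if teacher_state is not None:
        teacher_state.apply_to(net)
    samples = load_dataset(image_dir, mask_dir, target_size=net.config.input_size)
    maps = predict_samples(net, samples)
    return evaluate(maps, [s.mask for s in samples], threshold)


# -- regime comparison ----------------------------------------------------------

def run_regime_comparison(base_config: RunConfig, seeds: list[int],
                          regimes: tuple[str, ...] = REGIMES,
                          workdir=None) -> tuple[pd.DataFrame, dict]:
    """Train every regime for every seed on identical splits.

    Returns (summary table with mean/sd of each metric per regime,
    dict of (regime, seed) -> {"result": TrainingResult, "test": EvalResult}).
    """
    if not seeds:
        raise ValueError("need at least one seed")
    runs: dict = {}
    rows = []
    for seed in seeds:
        for regime in regimes:
            cfg = _replace_config(base_config, regime=regime, seed=seed, split_seed=seed)
            sub = None
            if workdir is not None:
                sub = Path(workdir) / f"{regime}_seed{seed}"
            result = train(cfg, workdir=sub)
            net = build_model(cfg.model, seed=0)
            if result.best_shadow:
                net.load_state_dict(result.best_shadow)
            test_maps = predict_samples(net, result.split.test)
            test_res = evaluate(test_maps, [s.mask for s in result.split.test])
            runs[(regime, seed)] = {"result": result, "test": test_res}
            rows.append({"regime": regime, "seed": seed, **test_res.to_dict()})
    per_run = pd.DataFrame(rows)
    summary = (per_run.groupby("regime", sort=False)
               [["dice", "jaccard", "accuracy", "recall", "precision"]]
               .agg(["mean", "std"]))
    return summary, {"runs": runs, "per_run": per_run}


def _replace_config(cfg: RunConfig, **updates) -> RunConfig:
    d = asdict(cfg)
    d["model"] = ModelConfig(**{**d["model"], "input_size": tuple(d["model"]["input_size"])})
    fx = d["data"]["fixture"]
    d["data"] = DataConfig(
        image_dir=d["data"]["image_dir"], mask_dir=d["data"]["mask_dir"],
        fixture=None if fx is None else FixtureConfig(**{
            **fx,
            "image_size": tuple(fx["image_size"]),
            "blobs_per_image": tuple(fx["blobs_per_image"]),
            "blob_radius_frac": tuple(fx["blob_radius_frac"]),
        }),
    )
    d["cupl"] = CuplConfig(**d["cupl"])
    d["ratios"] = tuple(d["ratios"])
    d["perturbations"] = tuple(d["perturbations"])
    d.update(updates)
    return RunConfig(**d)


# -- the desk-scale study protocol ---------------------------------------------

def fixture_protocol_config(seed: int = 0, regime: str = "cl_cupl",
                            epochs: int = 60) -> RunConfig:
    """The scaled-down study conditions: 64x64 fixtures, tiny backbone,
    20 labeled / 200 unlabeled, short schedule sized for a CPU."""
    return RunConfig(
        regime=regime,
        model=ModelConfig(backbone="tiny", levels=3, base_channels=8,
                          input_size=(64, 64)),
        data=DataConfig(fixture=FixtureConfig(n_images=375, image_size=(64, 64), seed=1234)),
        ratios=(0.8, 0.1, 0.1),
        n_labeled=20,
        n_unlabeled=200,
        epochs=epochs,
        batch_size=4,
        lr=2e-3,
        lambda_max=1.0,
        ramp_epochs=15,
        cupl=CuplConfig(update_interval_epochs=10, keep_fraction=0.8, warmup_epochs=40),
        seed=seed,
        alpha=0.99,
    )


# -- config (de)serialisation ---------------------------------------------------

def config_to_yaml(cfg: RunConfig) -> str:
    d = asdict(cfg)
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> RunConfig:
    d = yaml.safe_load(text)
    base = RunConfig()
    merged = {**asdict(base), **d}
    if merged.get("model"):
        m = {**asdict(base.model), **(d.get("model") or {})}
        m["input_size"] = tuple(m["input_size"])
        merged["model"] = ModelConfig(**m)
    dd = {**asdict(base.data), **(d.get("data") or {})}
    if dd.get("fixture"):
        fx = {**asdict(FixtureConfig()), **dd["fixture"]}
        fx["image_size"] = tuple(fx["image_size"])
        fx["blobs_per_image"] = tuple(fx["blobs_per_image"])
        fx["blob_radius_frac"] = tuple(fx["blob_radius_frac"])
        dd["fixture"] = FixtureConfig(**fx)
    merged["data"] = DataConfig(**dd)
    merged["cupl"] = CuplConfig(**{**asdict(base.cupl), **(d.get("cupl") or {})})
    merged["ratios"] = tuple(merged["ratios"])
    merged["perturbations"] = tuple(merged["perturbations"])
    return RunConfig(**merged)
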