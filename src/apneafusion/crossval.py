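"""K-fold cross-validation protocol with minority oversampling and
fold-wise image augmentation.

For each fold the test subset is isolated untouched; the remaining images
are (optionally) split again for checkpoint selection, the apnea minority
class is oversampled to parity by random duplication, and geometric
augmentation is re-drawn on every training batch. A freshly initialized
network is trained per fold and its best checkpoint (by validation
accuracy) is evaluated on the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from . import network as net_mod
from .metrics import ConfusionCounts, MetricSet, aggregate_folds, confusion, metric_set
from .network import NetworkSpec, TrainingConfig, TrainingHistory


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each item to one of k folds."""

    k: int
    seed: int
    assignments: np.ndarray

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


@dataclass
class AugmentConfig:
    """Ranges of the geometric augmentation, drawn uniformly per image:
    rotation +-8 deg, horizontal translation +-30 px, vertical translation
    +-10 px, shear +-5 deg, horizontal flip with probability 0.5."""

    rotation: float = 8.0
    h_translate: float = 30.0
    v_translate: float = 10.0
    shear: float = 5.0
    h_flip_prob: float = 0.5


def kfold_split(
    n_items: int, k: int, seed: int, labels: np.ndarray | None = None, stratify: bool = False
) -> FoldPlan:
    """Uniformly random partition into k near-equal folds (sizes differ by <= 1).

    With ``stratify=True`` (``labels`` required) each class is partitioned
    separately, reproducing protocols whose per-fold class counts are exact.
    """
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n_items, dtype=np.int64)
    if stratify:
        if labels is None:
            raise ValueError("stratified split requires labels")
        labels = np.asarray(labels)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            assignments[perm] = np.arange(len(perm)) % k
    else:
        perm = rng.permutation(n_items)
        # first (n % k) folds get the extra item
        sizes = np.full(k, n_items // k)
        sizes[: n_items % k] += 1
        assignments[perm] = np.repeat(np.arange(k), sizes)
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def oversample_minority(train_labels, seed: int) -> np.ndarray:
    """Indices into ``train_labels`` with the minority class resampled to parity.

    Majority indices appear exactly once; the minority class is augmented by
    sampling existing minority indices with replacement until class counts
    are equal. Already-balanced input is returned unchanged.
    """
    labels = np.asarray(train_labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires both classes present")
    if len(classes) > 2:
        raise ValueError("binary labels expected")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    base = np.arange(len(labels))
    if deficit == 0:
        return base
    minority_idx = np.flatnonzero(labels == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    return np.concatenate([base, extra])


def draw_augment_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Sample one set of augmentation parameters (each uniform in its range)."""
    return {
        "rotation": float(rng.uniform(-config.rotation, config.rotation)),
        "h_translate": float(rng.uniform(-config.h_translate, config.h_translate)),
        "v_translate": float(rng.uniform(-config.v_translate, config.v_translate)),
        "shear": float(rng.uniform(-config.shear, config.shear)),
        "flip": bool(rng.random() < config.h_flip_prob),
    }


def apply_augment(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply one drawn parameter set; exposed pixels are filled with 0."""
    out = image
    if params["flip"]:
        out = out[:, ::-1, :]
    if any(params[key] for key in ("rotation", "h_translate", "v_translate", "shear")):
        h, w = out.shape[:2]
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(
                rotation=np.deg2rad(params["rotation"]), shear=np.deg2rad(params["shear"])
            )
            + AffineTransform(
                translation=center + [params["h_translate"], params["v_translate"]]
            )
        )
        out = warp(out, tf.inverse, order=1, cval=0.0, preserve_range=True)
    return np.ascontiguousarray(out, dtype=image.dtype)


def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomly rotate, translate, shear and possibly flip one image."""
    return apply_augment(image, draw_augment_params(config, rng))


def _augment_batch(config: AugmentConfig):
    def fn(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.stack([augment(img, config, rng) for img in batch])

    return fn


@dataclass
class FoldResult:
    """Held-out evaluation of one fold."""

    fold: int
    counts: ConfusionCounts
    metrics: MetricSet
    history: TrainingHistory
    best_checkpoint: int
    test_indices: np.ndarray


@dataclass
class CVResult:
    """All folds plus the macro-averaged summary with 95% CIs."""

    folds: list[FoldResult]
    aggregate: dict[str, tuple[float, float]] = field(default_factory=dict)

    def per_fold_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            row = {"fold": fr.fold, **fr.metrics.as_dict()}
            row.update(tp=fr.counts.tp, tn=fr.counts.tn, fp=fr.counts.fp, fn=fr.counts.fn)
            rows.append(row)
        return pd.DataFrame(rows)

    def aggregate_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": name, "mean": mean, "ci95_half_width": half}
            for name, (mean, half) in self.aggregate.items()
        ]
        return pd.DataFrame(rows)


def run_cv(
    images: np.ndarray,
    labels,
    k: int = 10,
    train_config: TrainingConfig | None = None,
    augment_config: AugmentConfig | None = None,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    val_fraction: float = 0.1,
    validate_on_test: bool = False,
    group_ids=None,
) -> CVResult:
    """Run the full k-fold protocol and aggregate fold metrics.

    ``labels`` are 'N'/'A' strings. For each fold, the test subset is never
    oversampled or augmented (leakage is asserted); checkpoint selection
    uses a ``val_fraction`` carve-out of the training images, or the test
    fold itself when ``validate_on_test`` is set (optimistic, as some
    protocols do). ``group_ids``
    switches to a grouped split that keeps all minutes of one recording in
    a single fold.
    """
    labels = np.asarray(labels)
    images = np.asarray(images)
    if len(images) != len(labels):
        raise ValueError("images and labels must be parallel")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    if len(images) < k:
        raise ValueError(f"need at least k={k} items")
    train_config = train_config or TrainingConfig()
    augment_config = augment_config or AugmentConfig()
    spec = spec or NetworkSpec(input_shape=images.shape[1:])

    ss = np.random.SeedSequence(seed)
    split_seed = int(ss.generate_state(1)[0] % (2**31))
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]

    if group_ids is not None:
        plan = _grouped_split(np.asarray(group_ids), k, split_seed)
    else:
        plan = kfold_split(len(images), k, split_seed)

    y = (labels == "A").astype(np.int64)
    fold_results: list[FoldResult] = []
    for fold in range(k):
        frng = np.random.default_rng(fold_seeds[fold])
        test_idx = plan.fold_indices(fold)
        train_idx = np.flatnonzero(plan.assignments != fold)

        if validate_on_test:
            val_idx = test_idx
            fit_idx = train_idx
        else:
            n_val = max(int(round(val_fraction * len(train_idx))), 2)
            carve = frng.permutation(len(train_idx))
            val_idx = train_idx[carve[:n_val]]
            fit_idx = train_idx[carve[n_val:]]

        over = oversample_minority(labels[fit_idx], seed=int(frng.integers(2**31)))
        fit_idx_over = fit_idx[over]

        # leakage check: no held-out image may enter the training multiset
        assert not set(test_idx) & set(fit_idx_over), "test images leaked into training"
        if not validate_on_test:
            assert not set(test_idx) & set(val_idx), "test images leaked into validation"
        cls, cnt = np.unique(labels[fit_idx_over], return_counts=True)
        assert len(cls) == 2 and cnt[0] == cnt[1], "oversampling must balance classes"

        fold_cfg = TrainingConfig(
            **{
                **train_config.__dict__,
                "seed": int(frng.integers(2**31)),
            }
        )
        net, history = net_mod.train(
            spec,
            images[fit_idx_over],
            y[fit_idx_over],
            images[val_idx],
            y[val_idx],
            fold_cfg,
            augment_fn=_augment_batch(augment_config),
        )
        best = net_mod.select_best_checkpoint(history)
        net.set_weights(history.checkpoints[best])
        history.checkpoints.clear()  # weights restored; free the snapshots
        _, pred = net_mod.predict(net, images[test_idx], batch=fold_cfg.batch_size)
        pred_labels = np.where(pred == 1, "A", "N")
        counts = confusion(pred_labels, labels[test_idx])
        fold_results.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=metric_set(counts),
                history=history,
                best_checkpoint=best,
                test_indices=test_idx,
            )
        )

    aggregate = aggregate_folds([fr.metrics for fr in fold_results])
    return CVResult(folds=fold_results, aggregate=aggregate)


def _grouped_split(group_ids: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Assign whole groups (recordings) to folds, balancing fold sizes."""
    rng = np.random.default_rng(seed)
    groups = rng.permutation(np.unique(group_ids))
    if len(groups) < k:
        raise ValueError(f"need at least k={k} groups for a grouped split")
    fold_sizes = np.zeros(k, dtype=np.int64)
    assignments = np.empty(len(group_ids), dtype=np.int64)
    for g in groups:
        target = int(np.argmin(fold_sizes))
        members = np.flatnonzero(group_ids == g)
        assignments[members] = target
        fold_sizes[target] += len(members)
    return FoldPlan(k=k, seed=seed, assignments=assignments)
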