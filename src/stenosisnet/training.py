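"""Weighted cross-entropy training and the four-fold cross-validation driver.

Training minimizes the weighted cross-entropy error

    WCEE = -(1/n) * sum_i  w_i * <t_i, log y_i>

with stochastic gradient descent (momentum 0.9), batch size 4, learning rate
1e-4, for at most 50 epochs with early stopping on the validation WCEE.
Class weights counter the heavy class imbalance (stenosis prevalence is below
10%); by default they are inverse class frequencies, normalized to average 1,
computed on the training data the loss actually sees.

Cross-validation is patient-level: patients are split into four stenosis-
balanced folds, each rotation trains on two folds, early-stops on one and
scores the held-out test fold, so every segment receives exactly one
out-of-fold probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace as dc_replace

import numpy as np
import pandas as pd

from . import network as net
from .dataset import (
    Voi,
    apply_inclusion_filter,
    assign_folds,
    augment_positive,
    extract_voi,
    make_cv_splits,
    normalize_voi,
    patient_volume_mean,
)
from .network import NetworkConfig

logger = logging.getLogger(__name__)

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule hyperparameters (defaults are the study settings)."""

    batch_size: int = 4
    max_epochs: int = 50
    learning_rate: float = 1e-4
    momentum: float = 0.9
    class_weights: tuple[float, float] | str = "auto"
    patience: int = 5
    seed: int = 0
    # arithmetic precision of the SGD loop; single precision is the usual
    # convention for CNN training and is fully deterministic
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.class_weights != "auto":
            w = tuple(self.class_weights)
            if len(w) != 2 or any(x <= 0 for x in w):
                raise ValueError("class_weights must be 'auto' or two positive floats")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    def to_dict(self) -> dict:
        return asdict(self)


def wcee_loss(y: np.ndarray, t: np.ndarray, w: np.ndarray) -> float:
    """Weighted cross-entropy error of a batch.

    y: (n, 2) predicted probability vectors; t: (n, 2) one-hot true classes;
    w: (n,) weight of each example's true class. Probabilities are clamped at
    1e-12 before the log so the loss stays finite (clamping is logged).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(y[t > 0] < _LOG_EPS):
        logger.warning("predicted probability at the true class clamped to %g", _LOG_EPS)
    logy = np.log(np.clip(y, _LOG_EPS, None))
    return float(-(w * (t * logy).sum(axis=1)).mean())


def auto_class_weights(labels) -> np.ndarray:
    """Inverse-frequency class weights, normalized so the pair averages to 1.

    w_k = n_total / (2 * n_k); requires both classes present.
    """
    labels = np.asarray(labels)
    n = labels.size
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()])
    if np.any(counts == 0):
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * counts)


def _stack(vois: list[Voi]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([v.values for v in vois])[:, None]
    y = np.array([v.label for v in vois])
    return x, y


def train_one_split(
    train_vois: list[Voi],
    val_vois: list[Voi],
    net_config: NetworkConfig,
    train_config: TrainConfig,
) -> tuple[dict, list[dict]]:
    """SGD-momentum training with early stopping on the validation WCEE.

    The caller supplies the training set with positives already augmented;
    validation data are never augmented. Returns the parameters of the best
    validation epoch and the per-epoch loss history.
    """
    dtype = np.dtype(train_config.dtype)
    x_train, y_train = _stack(train_vois)
    x_val, y_val = _stack(val_vois)
    x_train = x_train.astype(dtype)
    x_val = x_val.astype(dtype)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    if train_config.class_weights == "auto":
        cw = auto_class_weights(y_train)
    else:
        cw = np.asarray(train_config.class_weights, dtype=float)
    cw = cw.astype(dtype)
    t_train = np.eye(2, dtype=dtype)[y_train]
    t_val = np.eye(2, dtype=dtype)[y_val]
    w_val = cw[y_val]

    params = {k: v.astype(dtype) for k, v in net.init_params(net_config).items()}
    velocity = {k: np.zeros_like(params[k]) for k in net.LEARNABLE_KEYS}
    rng = np.random.default_rng(train_config.seed)
    lr, mom, bs = train_config.learning_rate, train_config.momentum, train_config.batch_size

    history: list[dict] = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    wait = 0
    n = x_train.shape[0]
    for epoch in range(train_config.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            loss, grads = net.loss_and_grads(
                params, net_config, x_train[idx], t_train[idx], cw[y_train[idx]]
            )
            epoch_loss += loss * idx.size
            for k in net.LEARNABLE_KEYS:
                velocity[k] = mom * velocity[k] - lr * grads[k]
                params[k] = params[k] + velocity[k]
        train_loss = epoch_loss / n

        val_probs = np.concatenate([
            net.forward(x_val[i : i + 256], params, net_config, training=False)
            for i in range(0, x_val.shape[0], 256)
        ])
        val_loss = wcee_loss(val_probs, t_val, w_val)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train WCEE %.4f, val WCEE %.4f", epoch, train_loss, val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            wait = 0
        else:
            wait += 1
            if wait >= train_config.patience:
                logger.info("early stopping at epoch %d (best val WCEE %.4f)", epoch, best_val)
                break
    return best_params, history


def build_voi(volume: np.ndarray, record, volume_mean: float) -> Voi:
    """Extract, normalize and wrap the 21^3 patch around a record's annotation."""
    patch = extract_voi(volume, record.annotation)
    patch = np.maximum(normalize_voi(patch, volume_mean), 0.0)
    return Voi(
        values=patch,
        label=record.label,
        patient_id=record.patient_id,
        segment_id=record.segment_id,
    )


def run_cross_validation(
    records,
    volumes: dict[str, np.ndarray],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    seed: int = 0,
    return_models: bool = False,
):
    """Four-fold patient-level cross-validation producing pooled out-of-fold scores.

    ``records`` are segment records (or phantom truths) carrying patient_id,
    segment_id, annotation, label and the exclusion flags; ``volumes`` maps
    patient_id to its 3D volume. Returns a DataFrame with one row per retained
    segment: patient_id, segment_id, label, score, fold (and the per-fold
    histories; with ``return_models`` also the best parameters per fold).
    """
    retained = apply_inclusion_filter(list(records))
    means = {pid: patient_volume_mean(vol) for pid, vol in volumes.items()}
    vois = {
        r.segment_id: build_voi(volumes[r.patient_id], r, means[r.patient_id])
        for r in retained
    }

    assignment = assign_folds(retained, n_folds=4, seed=seed)
    splits = make_cv_splits(assignment)

    rows = []
    histories = []
    models = []
    for fold, (train_p, val_p, test_p) in enumerate(splits):
        train_vois: list[Voi] = []
        for r in retained:
            if r.patient_id not in train_p:
                continue
            v = vois[r.segment_id]
            train_vois.extend(augment_positive(v) if v.label == 1 else [v])
        val_vois = [vois[r.segment_id] for r in retained if r.patient_id in val_p]
        test_records = [r for r in retained if r.patient_id in test_p]

        fold_seed = int(np.random.SeedSequence((train_config.seed, fold)).generate_state(1)[0] % 2**31)
        fold_config = dc_replace(train_config, seed=fold_seed)
        logger.info(
            "fold %d: %d train VOIs (%d positive), %d val, %d test",
            fold, len(train_vois), sum(v.label for v in train_vois),
            len(val_vois), len(test_records),
        )
        params, history = train_one_split(train_vois, val_vois, net_config, fold_config)
        histories.append(history)
        if return_models:
            models.append(params)

        x_test = np.stack([vois[r.segment_id].values for r in test_records])[:, None]
        scores = net.predict_proba(x_test, params, net_config)
        for r, s in zip(test_records, scores):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "segment_id": r.segment_id,
                    "label": r.label,
                    "score": float(s),
                    "fold": fold,
                }
            )

    pooled = pd.DataFrame(rows)
    if return_models:
        return pooled, histories, models
    return pooled, histories
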