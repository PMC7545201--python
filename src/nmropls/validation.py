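"""Repeated k-fold cross-validation ensembles and permutation nulls.

Each iteration draws a fresh (stratified) k-fold partition, fits one
OPLS-DA model per training split and pools the held-out predictions so
every sample is predicted exactly once per iteration. The permutation
null repeats the identical procedure on labels shuffled once per
iteration; comparing the two ensembles yields an empirical p-value for
the observed accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .multivariate import ScalingSpec, fit_opls_da, predict
from .processing import BinnedMatrix

__all__ = [
    "CvConfig",
    "EnsembleResult",
    "ensemble_cv",
    "permutation_null",
    "compare_to_null",
]

_FOLD_STREAM = 0
_PERM_STREAM = 1


@dataclass
class CvConfig:
    k_folds: int = 10
    iterations: int = 100
    stratified: bool = True
    n_ortho: int = 1
    scaling: str = "unit_variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class EnsembleResult:
    """Per-iteration metric vectors plus mean +/- SEM summaries.

    SEM follows the sd/sqrt(iterations) convention: the unit of analysis
    is one iteration's pooled held-out predictions, not the individual
    fold models.
    """

    accuracy: np.ndarray  # %
    sensitivity: np.ndarray  # %
    specificity: np.ndarray  # %
    q2: np.ndarray
    r2x: np.ndarray
    r2y: np.ndarray
    label_mode: str  # "true" | "permuted"
    config: CvConfig
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"label_mode": self.label_mode, "iterations": self.config.iterations}
        for name in ("accuracy", "sensitivity", "specificity", "q2", "r2x", "r2y"):
            v = getattr(self, name)
            out[name] = {
                "mean": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            }
        return out

    def to_dict(self) -> dict:
        return {
            "per_iteration": {
                name: getattr(self, name).tolist()
                for name in ("accuracy", "sensitivity", "specificity", "q2", "r2x", "r2y")
            },
            "summary": self.summary(),
            "config": asdict(self.config),
        }


def _as_xy(X, y):
    if isinstance(X, BinnedMatrix):
        Xa = X.retained_values()
        ya = np.asarray(X.groups if y is None else y)
    else:
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y)
    return Xa, ya


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator, stratified: bool = True
) -> list[np.ndarray]:
    """Random k-fold partition; stratified deals each class round-robin
    after an in-class shuffle so fold class ratios stay near-constant."""
    n = y.size
    if stratified:
        folds: list[list[int]] = [[] for _ in range(k)]
        offset = 0
        for cls in sorted(set(y.tolist()), key=str):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, sample in enumerate(idx):
                folds[(j + offset) % k].append(int(sample))
            offset += idx.size % k
        out = [np.array(sorted(f), dtype=int) for f in folds]
    else:
        idx = rng.permutation(n)
        out = [np.array(sorted(part), dtype=int) for part in np.array_split(idx, k)]
    if any(f.size == 0 for f in out):
        raise ValueError(f"empty fold with k={k} and n={n}")
    return out


def _check_classes(y: np.ndarray, config: CvConfig) -> tuple:
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if config.stratified:
        for cls in classes:
            size = int((y == cls).sum())
            if size < config.k_folds:
                raise ValueError(
                    f"class {cls!r} has {size} samples < k_folds="
                    f"{config.k_folds}; lower k_folds"
                )
    return tuple(classes)


def _run_ensemble(X, y, config: CvConfig, positive_label, permute: bool) -> EnsembleResult:
    Xa, ya = _as_xy(X, y)
    classes = _check_classes(ya, config)
    if positive_label is None:
        positive_label = classes[-1]
    negative_label = classes[0] if classes[1] == positive_label else classes[1]

    iters = config.iterations
    acc = np.zeros(iters)
    sens = np.zeros(iters)
    spec = np.zeros(iters)
    q2 = np.zeros(iters)
    r2x = np.zeros(iters)
    r2y = np.zeros(iters)

    for it in range(iters):
        fold_rng = np.random.default_rng([config.seed, _FOLD_STREAM, it])
        y_it = ya
        if permute:
            perm_rng = np.random.default_rng([config.seed, _PERM_STREAM, it])
            y_it = ya[perm_rng.permutation(ya.size)]
        folds = stratified_folds(y_it, config.k_folds, fold_rng, config.stratified)

        pred_labels = np.empty(ya.size, dtype=object)
        pred_scores = np.zeros(ya.size)
        fold_r2x = np.zeros(len(folds))
        fold_r2y = np.zeros(len(folds))
        for fi, test_idx in enumerate(folds):
            train_mask = np.ones(ya.size, dtype=bool)
            train_mask[test_idx] = False
            model = fit_opls_da(
                Xa[train_mask],
                y_it[train_mask],
                n_ortho=config.n_ortho,
                scaling=config.scaling,
                positive_label=positive_label,
            )
            scores, labels = predict(model, Xa[test_idx])
            pred_labels[test_idx] = labels
            pred_scores[test_idx] = scores + model.y_mean
            fold_r2x[fi] = model.r2x
            fold_r2y[fi] = model.r2y

        truth = y_it
        coded = np.where(truth == positive_label, 1.0, -1.0)
        correct = pred_labels == truth
        acc[it] = 100.0 * correct.mean()
        pos = truth == positive_label
        neg = truth == negative_label
        sens[it] = 100.0 * correct[pos].mean()
        spec[it] = 100.0 * correct[neg].mean()
        press = float(((coded - pred_scores) ** 2).sum())
        ss = float(((coded - coded.mean()) ** 2).sum())
        q2[it] = 1.0 - press / ss
        r2x[it] = fold_r2x.mean()
        r2y[it] = fold_r2y.mean()

    return EnsembleResult(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        q2=q2,
        r2x=r2x,
        r2y=r2y,
        label_mode="permuted" if permute else "true",
        config=config,
        meta={"positive_label": positive_label, "n": int(ya.size)},
    )


def ensemble_cv(X, y=None, config: CvConfig | None = None, positive_label=None) -> EnsembleResult:
    """True-label repeated k-fold CV ensemble."""
    return _run_ensemble(X, y, config or CvConfig(), positive_label, permute=False)


def permutation_null(X, y=None, config: CvConfig | None = None, positive_label=None) -> EnsembleResult:
    """Permuted-label null ensemble: one fresh uniform label permutation
    per iteration, then the identical k-fold procedure."""
    return _run_ensemble(X, y, config or CvConfig(), positive_label, permute=True)


def compare_to_null(obs: EnsembleResult, null: EnsembleResult) -> dict:
    """Observed-vs-null deltas plus an empirical p-value for accuracy.

    p = (1 + #{null iterations with accuracy >= observed mean}) /
    (1 + iterations); its floor is therefore 1/(iterations+1).
    """
    if obs.label_mode != "true" or null.label_mode != "permuted":
        raise ValueError("expected obs.label_mode='true' and null.label_mode='permuted'")
    for attr in ("k_folds", "iterations", "stratified", "n_ortho", "scaling"):
        if getattr(obs.config, attr) != getattr(null.config, attr):
            raise ValueError(f"config mismatch on {attr!r}")
    obs_mean_acc = float(np.mean(obs.accuracy))
    n_iter = null.accuracy.size
    p = (1 + int((null.accuracy >= obs_mean_acc).sum())) / (1 + n_iter)
    report = {
        "p_accuracy": p,
        "observed": obs.summary(),
        "null": null.summary(),
    }
    for name in ("accuracy", "sensitivity", "specificity", "q2"):
        report[f"delta_{name}"] = float(
            np.mean(getattr(obs, name)) - np.mean(getattr(null, name))
        )
    return report
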