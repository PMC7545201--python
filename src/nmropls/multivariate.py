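"""PCA and OPLS-DA implemented from first principles.

OPLS-DA follows the standard orthogonal-projections scheme for a single
response: orthogonal components (X-variation uncorrelated with class) are
stripped first, then one predictive component is fitted on the deflated
matrix. With ``n_ortho=0`` the model is exactly a 1-component PLS1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .processing import BinnedMatrix

__all__ = [
    "ScalingSpec",
    "PcaResult",
    "OplsModel",
    "fit_pca",
    "fit_opls_da",
    "predict",
    "vip",
]

log = logging.getLogger(__name__)

SCALING_MODES = ("none", "center", "pareto", "unit_variance")


@dataclass
class ScalingSpec:
    """Column scaling learned from training rows only.

    pareto divides mean-centered columns by sqrt(sd); unit_variance by sd.
    Zero-variance columns get divisor 1 (logged).
    """

    mode: str = "unit_variance"
    center_: np.ndarray | None = None
    divisor_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in SCALING_MODES:
            raise ValueError(f"unknown scaling mode {self.mode!r}")

    def fit(self, X: np.ndarray) -> "ScalingSpec":
        X = np.asarray(X, dtype=float)
        if self.mode == "none":
            self.center_ = np.zeros(X.shape[1])
            self.divisor_ = np.ones(X.shape[1])
            return self
        self.center_ = X.mean(axis=0)
        if self.mode == "center":
            self.divisor_ = np.ones(X.shape[1])
            return self
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            log.warning("%d zero-variance columns scaled with divisor 1", zero.sum())
            sd = np.where(zero, 1.0, sd)
        self.divisor_ = np.sqrt(sd) if self.mode == "pareto" else sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center_ is None:
            raise ValueError("scaling not fitted")
        return (np.asarray(X, dtype=float) - self.center_) / self.divisor_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def clone_unfitted(self) -> "ScalingSpec":
        return ScalingSpec(mode=self.mode)


def _as_array(X) -> np.ndarray:
    if isinstance(X, BinnedMatrix):
        return X.retained_values()
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: np.ndarray  # n x k
    loadings: np.ndarray  # p x k, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scaling: ScalingSpec


def fit_pca(X, n_components: int, scaling: str | ScalingSpec = "pareto") -> PcaResult:
    """Principal component analysis via SVD of the scaled matrix."""
    Xa = _as_array(X)
    n, p = Xa.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, bins)="
            f"{min(n - 1, p)}"
        )
    spec = (
        scaling if isinstance(scaling, ScalingSpec) else ScalingSpec(mode=scaling)
    ).clone_unfitted()
    Xs = spec.fit(Xa).transform(Xa)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    var = s**2 / (n - 1)
    total_var = float((Xs**2).sum()) / (n - 1)
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        explained_variance=var,
        explained_variance_ratio=var / total_var,
        scaling=spec,
    )


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive component, ``n_ortho``
    orthogonal components).

    ``labels`` maps the coded classes: ``labels[+1]`` is the positive
    (treated-like) class, ``labels[-1]`` the control-like class. Ties at a
    predicted score of exactly 0 go to the control-like class.
    """

    w: np.ndarray  # predictive weights, unit norm
    t: np.ndarray  # predictive scores (training)
    p: np.ndarray  # predictive loadings
    c: float  # y-loading
    W_o: np.ndarray  # n_ortho x p orthogonal weights
    T_o: np.ndarray  # n x n_ortho orthogonal scores
    P_o: np.ndarray  # n_ortho x p orthogonal loadings
    scaling: ScalingSpec
    y_mean: float
    labels: dict[int, object]
    r2x: float
    r2y: float
    feature_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[0]

    @property
    def n_features(self) -> int:
        return self.w.size

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "c": self.c,
            "W_o": self.W_o.tolist(),
            "P_o": self.P_o.tolist(),
            "scaling": {
                "mode": self.scaling.mode,
                "center": self.scaling.center_.tolist(),
                "divisor": self.scaling.divisor_.tolist(),
            },
            "y_mean": self.y_mean,
            "labels": {str(k): str(v) for k, v in self.labels.items()},
            "r2x": self.r2x,
            "r2y": self.r2y,
            "n_ortho": self.n_ortho,
            "feature_names": self.feature_names,
        }


def _encode_labels(y, positive_label=None) -> tuple[np.ndarray, dict[int, object]]:
    y = np.asarray(y)
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if positive_label is None:
        positive_label = classes[-1]
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {classes}")
    negative_label = classes[0] if classes[1] == positive_label else classes[1]
    coded = np.where(y == positive_label, 1.0, -1.0)
    return coded, {1: positive_label, -1: negative_label}


def fit_opls_da(
    X,
    y,
    n_ortho: int = 1,
    scaling: str | ScalingSpec = "unit_variance",
    positive_label=None,
    feature_names: list[str] | None = None,
) -> OplsModel:
    """Fit OPLS-DA on a two-class cohort.

    Scaling parameters are learned from the given rows only; test samples
    must be pushed through :func:`predict`, which reuses them.
    """
    Xa = _as_array(X)
    if isinstance(X, BinnedMatrix) and feature_names is None:
        feature_names = X.retained_labels()
    coded, labels = _encode_labels(y, positive_label)
    n, p = Xa.shape
    if coded.size != n:
        raise ValueError("y length does not match X rows")
    for cls in (1.0, -1.0):
        if (coded == cls).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho >= min(n - 1, p):
        raise ValueError(
            f"n_ortho={n_ortho} too large for a {n}x{p} matrix "
            f"(must be < min(n-1, p) = {min(n - 1, p)})"
        )

    spec = (scaling if isinstance(scaling, ScalingSpec) else ScalingSpec(mode=scaling)).clone_unfitted()
    Xs = spec.fit(Xa).transform(Xa)
    y_mean = float(coded.mean())
    yc = coded - y_mean

    ss_x_total = float((Xs**2).sum())
    Xd = Xs.copy()
    W_o = np.zeros((n_ortho, p))
    T_o = np.zeros((n, n_ortho))
    P_o = np.zeros((n_ortho, p))
    for i in range(n_ortho):
        w = Xd.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            raise ValueError("degenerate fit: X carries no y-covariance")
        w /= w_norm
        t = Xd @ w
        pv = Xd.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        w_o_norm = np.linalg.norm(w_o)
        if w_o_norm < 1e-12:
            raise ValueError(
                f"orthogonal component {i + 1} is degenerate; lower n_ortho"
            )
        w_o /= w_o_norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[i], T_o[:, i], P_o[i] = w_o, t_o, p_o

    w = Xd.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("degenerate fit: X carries no y-covariance")
    w /= w_norm
    t = Xd @ w
    tt = float(t @ t)
    pv = Xd.T @ t / tt
    c = float(yc @ t / tt)

    resid = Xd - np.outer(t, pv)
    r2x = 1.0 - float((resid**2).sum()) / ss_x_total if ss_x_total > 0 else 0.0
    ss_y = float(yc @ yc)
    r2y = 1.0 - float(((yc - c * t) ** 2).sum()) / ss_y if ss_y > 0 else 0.0

    return OplsModel(
        w=w,
        t=t,
        p=pv,
        c=c,
        W_o=W_o,
        T_o=T_o,
        P_o=P_o,
        scaling=spec,
        y_mean=y_mean,
        labels=labels,
        r2x=float(np.clip(r2x, 0.0, 1.0)),
        r2y=float(np.clip(r2y, 0.0, 1.0)),
        feature_names=feature_names,
    )


def predict(model: OplsModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Predict continuous scores and class labels for new samples.

    New rows are scaled with the training parameters, deflated by the
    model's orthogonal components, then scored on the predictive weights.
    The continuous score is ``t_new * c`` (centered-response scale);
    classes are assigned by its sign with ties going to the control-like
    class.
    """
    Xa = _as_array(X_new)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    if Xa.shape[1] != model.n_features:
        raise ValueError(
            f"column mismatch: model has {model.n_features} features, input "
            f"has {Xa.shape[1]}"
        )
    Xs = model.scaling.transform(Xa)
    for i in range(model.n_ortho):
        t_o = Xs @ model.W_o[i]
        Xs = Xs - np.outer(t_o, model.P_o[i])
    t_new = Xs @ model.w
    y_hat = t_new * model.c
    if np.any(y_hat == 0):
        log.info("tie score(s) at 0 assigned to control-like class %r", model.labels[-1])
    classes = np.where(y_hat > 0, model.labels[1], model.labels[-1])
    return y_hat, classes


def vip(model: OplsModel) -> np.ndarray:
    """VIP scores on the predictive component: sqrt(K) * |w_j|.

    With a single predictive component the usual weighted-SSY formula
    collapses to this; the mean squared VIP over retained bins is 1.
    """
    K = model.n_features
    return np.sqrt(K) * np.abs(model.w)
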