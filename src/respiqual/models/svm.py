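"""Feature-based RBF-SVM quality classifier and its adapted (transfer) form.

The base classifier is a C-SVM with a radial basis function kernel whose box
constraint C and kernel scale gamma are chosen by Bayesian optimization of
the 5-fold cross-validated misclassification error, then refit on all
training data.

Transfer to a new population uses the adaptive-SVM formulation: the adapted
decision function is the frozen source decision function plus a kernel
perturbation learned on the new data,

    f_adapted(x) = f_src(x) + sum_i alpha_i y_i (K(x_i, x) + 1),

where the alphas solve the dual of  min 1/2 ||Delta f||^2 + C_a * sum slack
subject to margin constraints on the new data.  This minimizes the
classification error on the new data while penalizing dissimilarity from the
source model; the "+1" augmentation of the kernel absorbs a regularized bias
shift.  As C_a -> 0 the perturbation vanishes and the adapted model reduces
to the source model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ..core import ValidationError
from .bayesopt import bayes_minimize, unit_to_loguniform
from .common import platt_apply, platt_fit
from .config import AdaptationConfig

HYPER_RANGE = (1e-3, 1e3)  # log-uniform search box for both C and gamma


@dataclass
class SvmModel:
    """A trained RBF-SVM bundle (scaler + SVC + probability mapping)."""

    svc: SVC
    scaler: StandardScaler
    C: float
    gamma: float
    feature_names: tuple[str, ...]
    platt: tuple[float, float]
    seed: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        return self.svc.decision_function(self.scaler.transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the clean class; monotone in the SVM margin."""
        return platt_apply(self.decision_function(X), *self.platt)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class labels (1 = clean) from the sign of the margin."""
        return (self.decision_function(X) >= 0).astype(int)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected (n, {len(self.feature_names)}) feature matrix, got {X.shape}"
            )
        return X


def _cv_error(X: np.ndarray, y: np.ndarray, C: float, gamma: float, seed: int) -> float:
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    errs = []
    for tr, te in cv.split(X, y):
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[tr], y[tr])
        errs.append(np.mean(clf.predict(X[te]) != y[te]))
    return float(np.mean(errs))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
    n_calls: int = 25,
) -> SvmModel:
    """Train the RBF-SVM with Bayesian hyperparameter search.

    (C, gamma) are searched log-uniformly over [1e-3, 1e3]^2, scoring each
    pair by 5-fold cross-validated classification error; the best pair is
    refit on all the data and a Platt-style logistic maps decision values to
    clean-class probabilities.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("SVM training needs both classes present")
    if X.shape[0] < 10:
        raise ValidationError("SVM training needs at least 10 samples")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    def objective(u):
        C, gamma = unit_to_loguniform(u, *HYPER_RANGE)
        return _cv_error(Xs, y, C, gamma, seed)

    u_best, _, _, _ = bayes_minimize(objective, n_dims=2, n_calls=n_calls, seed=seed)
    C, gamma = (float(v) for v in unit_to_loguniform(u_best, *HYPER_RANGE))
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(Xs, y)
    platt = platt_fit(svc.decision_function(Xs), y)
    return SvmModel(
        svc=svc, scaler=scaler, C=C, gamma=gamma,
        feature_names=names, platt=platt, seed=seed,
    )


@dataclass
class AdaptedSvmModel:
    """Source SVM plus a learned kernel perturbation on new-domain data."""

    source: SvmModel
    X_adapt: np.ndarray          # scaled new-domain points carrying the perturbation
    coef: np.ndarray             # alpha_i * y_i, |alpha_i| <= C_a
    C_a: float
    platt: tuple[float, float]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.source.feature_names

    @property
    def gamma(self) -> float:
        return self.source.gamma

    def perturbation(self, X: np.ndarray) -> np.ndarray:
        Xs = self.source.scaler.transform(self.source._check(X))
        K = rbf_kernel(Xs, self.X_adapt, gamma=self.gamma) + 1.0
        return K @ self.coef

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.source.decision_function(X) + self.perturbation(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return platt_apply(self.decision_function(X), *self.platt)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    @property
    def perturbation_norm(self) -> float:
        """RKHS norm of the learned perturbation, ||Delta f||."""
        K = rbf_kernel(self.X_adapt, self.X_adapt, gamma=self.gamma) + 1.0
        return float(np.sqrt(max(self.coef @ K @ self.coef, 0.0)))


def adapt_svm(
    src: SvmModel,
    X_new: np.ndarray,
    y_new: np.ndarray,
    cfg: AdaptationConfig,
    feature_names: tuple[str, ...] | None = None,
    max_passes: int = 200,
    tol: float = 1e-8,
) -> AdaptedSvmModel:
    """Adapt a trained SVM to new-domain data (adaptive-SVM transfer).

    Solves the perturbation dual by box-constrained coordinate ascent:
    maximize  sum_i alpha_i (1 - y_i f_src(x_i)) - 1/2 sum_ij alpha_i
    alpha_j y_i y_j K'(x_i, x_j)  with 0 <= alpha_i <= C_a and
    K' = K_rbf + 1.  The same kernel scale as the source model is used; the
    new data must live in the source model's feature space.
    """
    if feature_names is not None and tuple(feature_names) != src.feature_names:
        raise ValidationError("adaptation features must match the source model's")
    X_new = src._check(X_new)
    y = np.asarray(y_new).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("adaptation needs both classes present")
    s = 2.0 * y - 1.0  # signed labels
    Xs = src.scaler.transform(X_new)
    f0 = src.svc.decision_function(Xs)
    K = rbf_kernel(Xs, Xs, gamma=src.gamma) + 1.0
    n = Xs.shape[0]
    alpha = np.zeros(n)
    f = f0.copy()  # current decision values on the adaptation set
    for _ in range(max_passes):
        max_delta = 0.0
        for i in range(n):
            g = 1.0 - s[i] * f[i]
            a_new = np.clip(alpha[i] + g / K[i, i], 0.0, cfg.svm_c_a)
            d = a_new - alpha[i]
            if d != 0.0:
                f += d * s[i] * K[:, i]
                alpha[i] = a_new
                max_delta = max(max_delta, abs(d))
        if max_delta < tol * max(cfg.svm_c_a, 1.0):
            break
    platt = platt_fit(f, y)
    return AdaptedSvmModel(
        source=src, X_adapt=Xs, coef=alpha * s, C_a=cfg.svm_c_a, platt=platt
    )
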