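"""Shared prediction interface for the SVM and CNN model bundles."""

from __future__ import annotations

import numpy as np


def platt_fit(decisions: np.ndarray, y: np.ndarray, n_iter: int = 200) -> tuple[float, float]:
    """Fit a logistic mapping p = sigmoid(a*d + b) of decision values to the
    positive class by Newton iterations.  Rank-preserving (a > 0 whenever the
    decisions separate the classes in the right direction), so it cannot
    change ROC/AUC — it only puts SVM scores on a probability scale."""
    d = np.asarray(decisions, dtype=float)
    t = np.asarray(y, dtype=float)
    a, b = 1.0, 0.0
    for _ in range(n_iter):
        z = np.clip(a * d + b, -35, 35)
        p = 1.0 / (1.0 + np.exp(-z))
        w = np.maximum(p * (1 - p), 1e-12)
        g = np.array([((p - t) * d).sum(), (p - t).sum()])
        h = np.array(
            [[(w * d * d).sum() + 1e-9, (w * d).sum()],
             [(w * d).sum(), w.sum() + 1e-9]]
        )
        step = np.linalg.solve(h, g)
        a, b = a - step[0], b - step[1]
        if np.abs(step).max() < 1e-10:
            break
    return float(a), float(b)


def platt_apply(decisions: np.ndarray, a: float, b: float) -> np.ndarray:
    z = np.clip(a * np.asarray(decisions, dtype=float) + b, -35, 35)
    return 1.0 / (1.0 + np.exp(-z))


def predict_proba(model, x) -> np.ndarray:
    """Probability of the *clean* class, for any model bundle exposing
    ``predict_proba`` (SVM on feature rows, CNN on waveforms)."""
    return model.predict_proba(x)
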