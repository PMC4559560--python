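"""Classifier training and confusion-matrix evaluation for beat datasets.

Classifiers: k-nearest-neighbour and SVM (scikit-learn), plus a small
feed-forward network (inputs-10-classes, tanh hidden / linear output, one-hot
targets) trained either by full-batch Levenberg-Marquardt (``mlp_lm``) or by
conjugate-gradient descent on the same MSE loss (``mlp_scg``).

Metrics follow the clinical convention with the normal class as positive:

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

where TP counts correctly classified normal beats and TN correctly classified
abnormal (bundle-branch-block) beats.  An empty denominator yields ``nan``
(an explicit undefined marker), never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .preprocessing import BeatDataset


@dataclass
class ClassifierSpec:
    """Which classifier to train and with what hyperparameters."""

    kind: str = "knn"  # knn | svm | mlp_lm | mlp_scg
    k: int = 1
    kernel: str = "rbf"
    regularization: float = 1.0
    hidden_units: int = 10
    max_iterations: int = 1000
    mse_goal: float = 1e-3
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"knn", "svm", "mlp_lm", "mlp_scg"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.mse_goal <= 0:
            raise ValueError("mse_goal must be > 0")

    def name(self) -> str:
        return {"knn": f"{self.k}-NN", "svm": "SVM",
                "mlp_lm": "LM NN", "mlp_scg": "SCG NN"}[self.kind]


@dataclass
class ClassificationReport:
    """One-vs-rest confusion counts and the percent metrics derived from them."""

    positive_class: int
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    per_class_accuracy: dict[int, float] = field(default_factory=dict)


class _Mlp:
    """Tanh-hidden / linear-output network on one-hot targets, argmax decision."""

    def __init__(self, n_in: int, n_hidden: int, classes: np.ndarray, seed: int):
        self.classes = classes
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, len(classes)
        rng = np.random.default_rng(seed)
        scale = 1.0 / math.sqrt(n_in)
        self.w1 = rng.normal(0.0, scale, (n_hidden, n_in))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, 1.0 / math.sqrt(n_hidden), (self.n_out, n_hidden))
        self.b2 = np.zeros(self.n_out)
        self.final_mse: float | None = None
        self.iterations: int = 0

    # --- parameter vector plumbing -------------------------------------
    def _pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def _unpack(self, p: np.ndarray) -> None:
        h, d, c = self.n_hidden, self.n_in, self.n_out
        i = 0
        self.w1 = p[i:i + h * d].reshape(h, d); i += h * d
        self.b1 = p[i:i + h]; i += h
        self.w2 = p[i:i + c * h].reshape(c, h); i += c * h
        self.b2 = p[i:i + c]

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.tanh(X @ self.w1.T + self.b1)
        return z, z @ self.w2.T + self.b2

    def _jacobian(self, X: np.ndarray, z: np.ndarray) -> np.ndarray:
        """d residual / d params, residuals ordered (sample, output)."""
        n, d, h, c = X.shape[0], self.n_in, self.n_hidden, self.n_out
        P = h * d + h + c * h + c
        J = np.zeros((n * c, P))
        dz = 1.0 - z ** 2                        # (n, h)
        # w1: dy_k/dW1_{ji} = w2_{kj} dz_j x_i
        g = self.w2[None, :, :] * dz[:, None, :]  # (n, c, h)
        J[:, : h * d] = (g[:, :, :, None] * X[:, None, None, :]).reshape(n * c, h * d)
        J[:, h * d: h * d + h] = g.reshape(n * c, h)
        off = h * d + h
        # w2: dy_k/dW2_{kj} = z_j (block-diagonal in k)
        Jw2 = np.zeros((n, c, c, h))
        for k in range(c):
            Jw2[:, k, k, :] = z
        J[:, off: off + c * h] = Jw2.reshape(n * c, c * h)
        off += c * h
        Jb2 = np.zeros((n, c, c))
        idx = np.arange(c)
        Jb2[:, idx, idx] = 1.0
        J[:, off:] = Jb2.reshape(n * c, c)
        return J

    # --- training -------------------------------------------------------
    def fit_lm(self, X: np.ndarray, T: np.ndarray, max_iter: int, mse_goal: float) -> None:
        """Damped Gauss-Newton (Levenberg-Marquardt), lambda x10 / /10 on fail/success."""
        lam = 1e-2
        p = self._pack()
        z, y = self._forward(X)
        r = (y - T).ravel()
        mse = float(np.mean(r ** 2))
        for it in range(max_iter):
            if mse <= mse_goal or lam > 1e10:
                break
            J = self._jacobian(X, z)
            g = J.T @ r
            H = J.T @ J
            improved = False
            while lam <= 1e10:
                try:
                    step = np.linalg.solve(H + lam * np.eye(len(p)), g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                p_new = p - step
                self._unpack(p_new)
                z_new, y_new = self._forward(X)
                r_new = (y_new - T).ravel()
                mse_new = float(np.mean(r_new ** 2))
                if mse_new < mse:
                    p, z, r, mse = p_new, z_new, r_new, mse_new
                    lam = max(lam / 10.0, 1e-12)
                    improved = True
                    break
                lam *= 10.0
            if not improved:
                self._unpack(p)
                break
            self.iterations = it + 1
        self._unpack(p)
        self.final_mse = mse

    def fit_cg(self, X: np.ndarray, T: np.ndarray, max_iter: int, mse_goal: float) -> None:
        """Conjugate-gradient minimization of the same MSE loss."""
        n = X.shape[0]

        def loss(p: np.ndarray) -> float:
            self._unpack(p)
            _, y = self._forward(X)
            return float(np.mean((y - T) ** 2))

        def grad(p: np.ndarray) -> np.ndarray:
            self._unpack(p)
            z, y = self._forward(X)
            r = (y - T).ravel()
            return 2.0 / r.size * (self._jacobian(X, z).T @ r)

        res = minimize(loss, self._pack(), jac=grad, method="CG",
                       options={"maxiter": max_iter, "gtol": 1e-10})
        self._unpack(res.x)
        self.final_mse = float(res.fun)
        self.iterations = int(res.nit)

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, y = self._forward(np.asarray(X, dtype=float))
        return self.classes[np.argmax(y, axis=1)]


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Train the classifier described by ``spec``; returns a model with .predict."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if spec.kind in {"svm", "mlp_lm", "mlp_scg"} and len(classes) < 2:
        raise ValueError(f"{spec.kind} requires at least 2 classes in the training set")
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k).fit(X, y)
    if spec.kind == "svm":
        return SVC(kernel=spec.kernel, C=spec.regularization).fit(X, y)
    net = _Mlp(X.shape[1], spec.hidden_units, classes, spec.train_seed)
    T = np.zeros((len(y), len(classes)))
    T[np.arange(len(y)), np.searchsorted(classes, y)] = 1.0
    if spec.kind == "mlp_lm":
        net.fit_lm(X, T, spec.max_iterations, spec.mse_goal)
    else:
        net.fit_cg(X, T, spec.max_iterations, spec.mse_goal)
    return net


def evaluate(predictions: np.ndarray, truth: np.ndarray, positive_class: int = 0) -> ClassificationReport:
    """One-vs-rest confusion tabulation with percent metrics.

    ``positive_class`` plays the role of the normal beats; every other class
    is pooled as abnormal.  Undefined ratios (empty denominators) are reported
    as ``nan``.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if predictions.size == 0:
        raise ValueError("need at least one sample")

    def ovr(pos: int) -> tuple[int, int, int, int]:
        pred_pos = predictions == pos
        true_pos = truth == pos
        tp = int(np.sum(pred_pos & true_pos))
        tn = int(np.sum(~pred_pos & ~true_pos))
        fp = int(np.sum(pred_pos & ~true_pos))
        fn = int(np.sum(~pred_pos & true_pos))
        return tp, tn, fp, fn

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    tp, tn, fp, fn = ovr(positive_class)
    per_class = {}
    for cls in np.unique(np.concatenate([truth, predictions])):
        ctp, ctn, cfp, cfn = ovr(int(cls))
        per_class[int(cls)] = pct(ctp + ctn, ctp + ctn + cfp + cfn)
    return ClassificationReport(
        positive_class=int(positive_class),
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        accuracy=pct(tp + tn, tp + tn + fp + fn),
        per_class_accuracy=per_class,
    )


def run_experiment(
    dataset: BeatDataset,
    subset,
    specs: list[ClassifierSpec],
    split_seed: int = 0,
    train_fraction: float = 0.65,
    positive_class: str = "NORMAL",
) -> pd.DataFrame:
    """Stratified train/test split, one report per classifier spec.

    Returns a table with columns (classifier, sensitivity_pct, specificity_pct,
    accuracy_pct); the split and every trainer are seed-deterministic.
    """
    X = dataset.matrix[:, subset.columns()] if subset is not None else dataset.matrix
    y = dataset.labels
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=split_seed, stratify=y,
    )
    pos = dataset.class_map[positive_class]
    rows = []
    for spec in specs:
        model = train_classifier(X_tr, y_tr, spec)
        report = evaluate(model.predict(X_te), y_te, positive_class=pos)
        rows.append({
            "classifier": spec.name(),
            "sensitivity_pct": report.sensitivity,
            "specificity_pct": report.specificity,
            "accuracy_pct": report.accuracy,
        })
    return pd.DataFrame(rows)
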