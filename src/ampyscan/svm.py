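"""Multiclass max-margin classification of composition feature vectors.

A one-vs-rest support vector machine with an inhomogeneous polynomial
kernel K(x, y) = (x.y + 1)**degree, sharing a single trade-off constant C
across classes.  Compositions already live in [0, 1], so no feature scaling
is applied.  After training, only the support vectors, dual coefficients
and intercepts are retained; decision values are computed directly from
them, so a model serialised to the JSON container reloads bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import SVC

_TOL = 1e-4


def _as_2d(X, n_features: int | None = None):
    """Coerce to a 2-D matrix; sparse input stays sparse."""
    if not sparse.issparse(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} features, got {X.shape[1]}")
    return X


@dataclass
class SVMModel:
    """Trained one-vs-rest polynomial SVM in explicit dual form.

    For class c the decision value of a vector x is
    ``sum_i alpha_ci * (sv_ci . x + 1)**degree + b_c``.
    """

    classes: list[str]
    C: float
    degree: int
    n_features: int
    support_vectors: list  # per class, (n_sv, n_features) dense or CSR
    dual_coef: list[np.ndarray]  # per class, shape (n_sv,)
    intercepts: list[float]
    ks: tuple[int, ...] | None = None  # feature layout (k-mer blocks)
    scheme: str = "one-vs-rest"
    seed: int = 0

    def decision_values(self, X) -> np.ndarray:
        """Per-class decision values, shape (n_samples, n_classes)."""
        X = _as_2d(X, self.n_features)
        cols = []
        for sv, alpha, b in zip(self.support_vectors, self.dual_coef, self.intercepts):
            inner = X @ sv.T
            if sparse.issparse(inner):
                inner = np.asarray(inner.todense())
            kernel = (inner + 1.0) ** self.degree
            cols.append(kernel @ alpha + b)
        return np.column_stack(cols)

    def predict(self, X) -> list[str]:
        """Argmax-of-decision-value labels; ties break by class order."""
        dv = self.decision_values(X)
        return [self.classes[i] for i in np.argmax(dv, axis=1)]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ampyscan-svm-v1",
            "classes": self.classes,
            "C": self.C,
            "degree": self.degree,
            "n_features": self.n_features,
            "ks": list(self.ks) if self.ks else None,
            "scheme": self.scheme,
            "seed": self.seed,
            "support_vectors": [
                (np.asarray(sv.todense()) if sparse.issparse(sv) else sv).tolist()
                for sv in self.support_vectors
            ],
            "dual_coef": [a.tolist() for a in self.dual_coef],
            "intercepts": self.intercepts,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SVMModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ampyscan-svm-v1":
            raise ValueError("not an ampyscan SVM model file")
        return cls(
            classes=payload["classes"],
            C=payload["C"],
            degree=payload["degree"],
            n_features=payload["n_features"],
            support_vectors=[np.array(sv) for sv in payload["support_vectors"]],
            dual_coef=[np.array(a) for a in payload["dual_coef"]],
            intercepts=list(payload["intercepts"]),
            ks=tuple(payload["ks"]) if payload["ks"] else None,
            scheme=payload["scheme"],
            seed=payload["seed"],
        )


def train_multiclass(
    X,
    y: Sequence[str],
    C: float = 0.01,
    degree: int = 3,
    ks: tuple[int, ...] | None = None,
    seed: int = 0,
) -> SVMModel:
    """Train a one-vs-rest polynomial-kernel SVM.

    The kernel is fixed to the inhomogeneous polynomial form and the
    trade-off constant C is the tunable hyperparameter (values such as 0.01
    and 0.001 are typical for composition features).  One binary soft-margin
    machine is fit per class against the rest; training is deterministic
    given the data.
    """
    Xfit = _as_2d(X)
    y = [str(v) for v in y]
    if Xfit.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if C <= 0:
        raise ValueError("C must be positive")
    data = Xfit.data if sparse.issparse(Xfit) else Xfit
    if not np.all(np.isfinite(data)):
        raise ValueError("features contain NaN or infinity")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    support_vectors, dual_coef, intercepts = [], [], []
    yarr = np.array(y)
    for c in classes:
        ybin = np.where(yarr == c, 1, -1)
        svc = SVC(
            kernel="poly",
            degree=degree,
            gamma=1.0,
            coef0=1.0,
            C=C,
            tol=_TOL,
            max_iter=200_000,
        )
        svc.fit(Xfit, ybin)
        # libsvm orients the decision function towards classes_[1]; with
        # ybin in {-1, +1}, classes_ is [-1, 1], so positive means class c
        support_vectors.append(svc.support_vectors_)
        dc = svc.dual_coef_
        if sparse.issparse(dc):
            dc = np.asarray(dc.todense())
        dual_coef.append(np.asarray(dc).ravel().copy())
        intercepts.append(float(svc.intercept_[0]))
    return SVMModel(
        classes=classes,
        C=C,
        degree=degree,
        n_features=Xfit.shape[1],
        support_vectors=support_vectors,
        dual_coef=dual_coef,
        intercepts=intercepts,
        ks=ks,
        seed=seed,
    )
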