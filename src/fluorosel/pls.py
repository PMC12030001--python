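"""Single-response partial least squares (PLS1) with cross-validated
component selection.

PLS builds orthogonal latent variables that maximize covariance with the
response, which makes it the standard regression for wide, collinear
predictor blocks such as fluorescence transients.  The estimator here is
a from-scratch NIPALS PLS1 wrapped in the scikit-learn estimator
protocol (``fit`` / ``predict`` / ``get_params`` / ``set_params``,
fitted attributes with a trailing underscore), so it composes with
sklearn pipelines and model selection without depending on sklearn.

The number of latent variables is chosen by ten-fold cross-validation:
RMSEP(k) is the root mean square of the pooled out-of-fold residuals at
k components, and the selected k is the smallest count attaining the
minimum over k >= 1 (the k = 0 per-fold-mean model is reported for
reference but never selected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


class NipalsPLS1:
    """NIPALS PLS1 regression estimator.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.
    scale : bool
        If True, predictors are autoscaled to unit variance after mean
        centering (appropriate for blocks with heterogeneous units such
        as biophysical parameters); if False only mean centering is
        applied (homogeneous blocks such as raw fluorescence readings).

    Attributes
    ----------
    x_weights_ : (p, k) NIPALS weight vectors W.
    x_loadings_ : (p, k) predictor loadings P.
    y_loadings_ : (k,) response loadings q.
    x_rotations_ : (p, k) rotation R = W (P'W)^-1 mapping X to scores.
    x_scores_ : (n, k) orthogonal training scores T.
    coef_path_ : (p, k+1) regression coefficients (centered/scaled space)
        for every component count 0..k.
    n_components_ : effective number of extracted components (may be
        smaller than requested when the predictor block is exhausted).
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "scale": self.scale}

    def set_params(self, **params) -> "NipalsPLS1":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y) -> "NipalsPLS1":
        Xm, names = _as_matrix(X)
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xm.shape
        if len(yv) != n:
            raise ValueError("X and y have incompatible lengths")
        if n < 2:
            raise ValueError("need at least two rows")
        if np.ptp(yv) == 0:
            raise ValueError("constant response: PLS1 is undefined")
        k_req = int(self.n_components)
        if k_req < 0 or k_req > min(n - 1, p):
            raise ValueError(
                f"n_components must be in [0, min(n-1, p)] = "
                f"[0, {min(n - 1, p)}]")

        self.feature_names_in_ = names
        self.x_mean_ = Xm.mean(axis=0)
        if self.scale:
            sd = Xm.std(axis=0, ddof=1)
            const = sd == 0
            if const.any():
                warnings.warn(
                    f"{int(const.sum())} constant predictor column(s); "
                    "their scale is set to 1", stacklevel=2)
                sd = np.where(const, 1.0, sd)
            self.x_scale_ = sd
        else:
            self.x_scale_ = np.ones(p)
        self.y_mean_ = float(yv.mean())

        Xc = (Xm - self.x_mean_) / self.x_scale_
        yc = yv - self.y_mean_

        W = np.zeros((p, k_req))
        P = np.zeros((p, k_req))
        q = np.zeros(k_req)
        T = np.zeros((n, k_req))
        Xd = Xc.copy()
        norm0 = np.linalg.norm(Xc.T @ yc)
        k_eff = 0
        for k in range(k_req):
            w = Xd.T @ yc
            nw = np.linalg.norm(w)
            if norm0 == 0 or nw <= 1e-12 * max(norm0, 1.0):
                warnings.warn(
                    f"predictor block exhausted after {k_eff} components "
                    f"({k_req} requested)", stacklevel=2)
                break
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                break
            W[:, k] = w
            P[:, k] = Xd.T @ t / tt
            q[k] = float(yc @ t) / tt
            T[:, k] = t
            Xd -= np.outer(t, P[:, k])
            k_eff += 1

        W, P, q, T = W[:, :k_eff], P[:, :k_eff], q[:k_eff], T[:, :k_eff]
        if k_eff:
            R = W @ np.linalg.inv(np.triu(P.T @ W))
        else:
            R = np.zeros((p, 0))
        coef_path = np.zeros((p, k_eff + 1))
        for k in range(1, k_eff + 1):
            coef_path[:, k] = R[:, :k] @ q[:k]

        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        self.x_rotations_, self.x_scores_ = R, T
        self.coef_path_ = coef_path
        self.coef_ = coef_path[:, k_eff]
        self.n_components_ = k_eff
        return self

    def predict(self, X, k: int | None = None) -> np.ndarray:
        """Predict with the first ``k`` latent variables (default: all)."""
        if not hasattr(self, "coef_path_"):
            raise ValueError("estimator is not fitted")
        if k is None:
            k = self.n_components_
        if not 0 <= k <= self.n_components_:
            raise ValueError(f"k must be in [0, {self.n_components_}]")
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            unknown = [c for c in X.columns if c not in self.feature_names_in_]
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if unknown or missing:
                raise ValueError(
                    f"predictor columns do not match training columns; "
                    f"unknown={unknown!r}, missing={missing!r}")
            Xm = X[self.feature_names_in_].to_numpy(dtype=float)
        else:
            Xm, _ = _as_matrix(X)
        Xc = (Xm - self.x_mean_) / self.x_scale_
        return self.y_mean_ + Xc @ self.coef_path_[:, k]

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "coef_path_")

    def __sklearn_tags__(self):
        # lazy import: only evaluated when scikit-learn tooling asks
        from sklearn.utils import RegressorTags, Tags, TargetTags
        return Tags(estimator_type="regressor",
                    target_tags=TargetTags(required=True),
                    regressor_tags=RegressorTags())

    def score(self, X, y, k: int | None = None) -> float:
        """Coefficient of determination R^2 (sklearn regressor protocol)."""
        yv = np.asarray(y, dtype=float).ravel()
        resid = yv - self.predict(X, k=k)
        return 1.0 - float(resid @ resid) / float(
            ((yv - yv.mean()) ** 2).sum())

    def fitted_values(self, k: int | None = None) -> np.ndarray:
        if k is None:
            k = self.n_components_
        return self.y_mean_ + self.x_scores_[:, :k] @ self.y_loadings_[:k]


def fit_pls(X, y, n_components: int, scale: bool = False) -> NipalsPLS1:
    """Functional wrapper over :class:`NipalsPLS1`."""
    return NipalsPLS1(n_components=n_components, scale=scale).fit(X, y)


def predict(model: NipalsPLS1, X_new, k: int | None = None) -> np.ndarray:
    """Functional wrapper over :meth:`NipalsPLS1.predict`."""
    return model.predict(X_new, k=k)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class RMSEPCurve:
    """Cross-validated RMSEP per component count.

    ``ks[0] = 0`` is the per-fold mean (null) model.  ``oof[:, k]``
    holds the pooled out-of-fold predictions at k components, so any
    downstream quantity (explained variance, predicted-trait tables)
    can reuse exactly the predictions behind the curve.
    """

    ks: np.ndarray
    rmsep: np.ndarray
    fold_assignment: np.ndarray
    seed: int
    oof: np.ndarray = field(repr=False)

    @property
    def selected(self) -> int:
        return select_components(self)

    def min_rmsep(self) -> float:
        return float(self.rmsep[self.selected])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_components": self.ks, "rmsep": self.rmsep})


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded near-equal random partition; returns fold index per row."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    return assignment


def cross_validate(
    X,
    y,
    max_components: int | None = None,
    folds: int = 10,
    seed: int = 0,
    scale: bool = False,
    fold_assignment: np.ndarray | None = None,
) -> RMSEPCurve:
    """Ten-fold (by default) cross-validated RMSEP curve.

    RMSEP(k) is computed on the pooled out-of-fold residuals, not as an
    average of per-fold RMSEPs.  ``max_components`` defaults to
    ``min(n - ceil(n/folds) - 1, p)`` and is truncated with a warning
    when a training split cannot support it.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one row per fold")
    if fold_assignment is None:
        fold_assignment = make_folds(n, folds, seed)
    else:
        fold_assignment = np.asarray(fold_assignment)
        folds = int(fold_assignment.max()) + 1

    largest_test = max(np.bincount(fold_assignment))
    cap = min(n - largest_test - 1, p)
    if max_components is None:
        max_components = cap
    elif max_components > cap:
        warnings.warn(
            f"max_components truncated from {max_components} to {cap}",
            stacklevel=2)
        max_components = cap

    oof = np.full((n, max_components + 1), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-exhaustion inside folds
        for f in range(folds):
            test = fold_assignment == f
            model = NipalsPLS1(n_components=max_components, scale=scale).fit(
                Xm[~test], yv[~test])
            for k in range(max_components + 1):
                kk = min(k, model.n_components_)
                oof[test, k] = model.predict(Xm[test], k=kk)
    rmsep = np.sqrt(np.mean((yv[:, None] - oof) ** 2, axis=0))
    return RMSEPCurve(
        ks=np.arange(max_components + 1), rmsep=rmsep,
        fold_assignment=fold_assignment, seed=seed, oof=oof)


def select_components(curve: RMSEPCurve) -> int:
    """Smallest k >= 1 attaining the minimum RMSEP (ties -> fewest)."""
    ks = np.asarray(curve.ks)
    rmsep = np.asarray(curve.rmsep)
    keep = ks >= 1
    if not keep.any():
        raise ValueError("empty RMSEP curve")
    ks, rmsep = ks[keep], rmsep[keep]
    return int(ks[np.argmin(rmsep)])


def explained_variance(y, y_pred) -> float:
    """Percent variance explained: 100 * (Pearson r of y and y_hat)^2.

    Conventionally evaluated on the out-of-fold cross-validated
    predictions at the selected component count.
    """
    yv = np.asarray(y, dtype=float).ravel()
    pv = np.asarray(y_pred, dtype=float).ravel()
    if len(yv) != len(pv) or len(yv) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(yv) == 0 or np.ptp(pv) == 0:
        warnings.warn("zero variance: explained variance undefined",
                      stacklevel=2)
        return float("nan")
    r = np.corrcoef(yv, pv)[0, 1]
    return float(100.0 * r * r)
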