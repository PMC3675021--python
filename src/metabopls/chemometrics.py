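"""Latent-variable models: NIPALS PCA, PLS1 discriminant analysis, and
single-response OPLS with an orthogonal signal correction filter.

All fitting routines expect a column-scaled matrix (see
:class:`~metabopls.preprocess.ScaledMatrix`); the class response is coded
+1 = control, -1 = COPD and centered internally, so positive model
coefficients correspond to variables elevated in healthy controls.

Model quality is summarized by R²X (fraction of X variation captured),
R²Y (fraction of class variation fitted) and Q² (cross-validated
predictability, ``1 - PRESS/SS``); Q² > 0.1 is conventionally treated as
an acceptable discriminant model and is reported as a flag, never
enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

from .preprocess import ScaledMatrix

__all__ = [
    "PCAModel",
    "PLSModel",
    "OPLSModel",
    "fit_pca",
    "hotelling_t2",
    "fit_pls",
    "predict_pls",
    "fit_opls",
    "predict_opls",
    "q2_score",
    "stratified_folds",
    "cross_validated_q2",
    "autofit_components",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAXITER = 500
Q2_ACCEPTABLE = 0.1  # conventional floor for a usable discriminant model


def _as_array(X) -> np.ndarray:
    if isinstance(X, ScaledMatrix):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("response has a single class; supervised fit needs both")


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A, orthonormal columns
    explained_fraction: np.ndarray  # per component
    cumulative_r2x: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _fix_sign(vec: np.ndarray, *companions: np.ndarray) -> None:
    """Flip so the largest-|value| entry of ``vec`` is positive (in place)."""
    j = int(np.argmax(np.abs(vec)))
    if vec[j] < 0:
        vec *= -1.0
        for c in companions:
            c *= -1.0


def fit_pca(X, A: int) -> PCAModel:
    """NIPALS principal component analysis of a centered/scaled matrix.

    Deterministic up to component sign, which is fixed so the
    largest-magnitude loading entry of each component is positive.
    """
    E = _as_array(X).copy()
    n, p = E.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if A < 1:
        raise ValueError("number of components must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    total = float((E**2).sum())
    if total == 0:
        raise ValueError("matrix has zero variance")
    T = np.empty((n, A))
    P = np.empty((p, A))
    explained = np.empty(A)
    for a in range(A):
        t = E[:, int(np.argmax(E.var(axis=0)))].copy()
        if not np.any(t):
            t = E[:, 0].copy()
        for _ in range(_NIPALS_MAXITER):
            pv = E.T @ t / (t @ t)
            pv /= np.linalg.norm(pv)
            t_new = E @ pv
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        _fix_sign(pv, t)
        T[:, a] = t
        P[:, a] = pv
        explained[a] = (t @ t) / total
        E -= np.outer(t, pv)
    return PCAModel(
        scores=T,
        loadings=P,
        explained_fraction=explained,
        cumulative_r2x=np.cumsum(explained),
    )


def hotelling_t2(model: PCAModel, alpha: float = 0.05):
    """Hotelling T² of each sample in score space with its F-based limit.

    ``T²_i = sum_a t_ia² / λ_a`` with λ_a the variance of score column a;
    the limit is ``A (N-1)(N+1) / (N (N-A)) * F_{1-α}(A, N-A)``.
    """
    T = model.scores
    N, A = T.shape
    if N <= A:
        raise ValueError(f"need more samples ({N}) than components ({A})")
    lam = T.var(axis=0, ddof=1)
    if np.any(lam <= 0):
        raise ValueError("zero-variance score column; reduce the component count")
    t2 = ((T**2) / lam).sum(axis=1)
    limit = A * (N - 1) * (N + 1) / (N * (N - A)) * st.f.ppf(1 - alpha, A, N - A)
    return t2, float(limit), t2 > limit


# ---------------------------------------------------------------------------
# PLS1

@dataclass
class PLSModel:
    weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    y_loadings: np.ndarray  # A
    y_mean: float
    r2x: float
    r2y: float
    q2: float | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def coef(self) -> np.ndarray:
        """Regression vector: ŷ = X @ coef + y_mean."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X, y, A: int) -> PLSModel:
    """NIPALS PLS1: for each component ``w ∝ X'y, t = Xw, p = X't/t't,
    q = y't/t't`` followed by deflation of X and y."""
    E = _as_array(X).copy()
    y = np.asarray(y, dtype=float)
    n, p = E.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    _check_two_classes(y)
    if A < 1:
        raise ValueError("number of components must be >= 1")
    y_mean = float(y.mean())
    f = y - y_mean
    ssx0 = float((E**2).sum())
    ssy0 = float((f**2).sum())
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    for a in range(A):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.sqrt(ssx0)):
            raise ValueError(f"component {a + 1} exceeds the rank of X")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-24 * max(1.0, ssx0):
            raise ValueError(f"component {a + 1} exceeds the rank of X")
        pv = E.T @ t / tt
        qa = float(f @ t) / tt
        E -= np.outer(t, pv)
        f = f - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pv, t, qa
    r2x = 1.0 - float((E**2).sum()) / ssx0
    r2y = 1.0 - float((f**2).sum()) / ssy0
    return PLSModel(W, P, T, q, y_mean, r2x, r2y)


def predict_pls(model: PLSModel, X_new) -> np.ndarray:
    X_new = _as_array(X_new)
    if X_new.shape[-1] != model.weights.shape[0]:
        raise ValueError(
            f"column mismatch: got {X_new.shape[-1]}, model has {model.weights.shape[0]}"
        )
    return X_new @ model.coef + model.y_mean


# ---------------------------------------------------------------------------
# OPLS (single y)

@dataclass
class OPLSModel:
    """One predictive component plus ``n_ortho`` orthogonal (OSC) components."""

    w: np.ndarray  # predictive weight, unit norm
    t: np.ndarray  # predictive score
    p: np.ndarray  # predictive loading
    q: float  # y loading
    W_o: np.ndarray  # p x n_ortho
    T_o: np.ndarray  # n x n_ortho
    P_o: np.ndarray  # p x n_ortho
    y_mean: float
    r2x_pred: float
    r2x_orth: float
    r2y: float
    q2: float | None = None

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    @property
    def r2x(self) -> float:
        return self.r2x_pred + self.r2x_orth


def fit_opls(X, y, n_ortho: int) -> OPLSModel:
    """Single-y OPLS: iteratively split off X variation orthogonal to the
    class response, then fit one predictive PLS component on the filtered
    matrix.  ``n_ortho = 0`` reduces exactly to one-component PLS.

    For a single response the predictive weight ``w ∝ X'y`` is invariant
    under orthogonal deflation (each orthogonal score has zero covariance
    with y), which is what makes OPLS predictions equivalent to those of a
    PLS model with ``n_ortho + 1`` components.
    """
    E = _as_array(X).copy()
    y = np.asarray(y, dtype=float)
    n, p = E.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    _check_two_classes(y)
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    y_mean = float(y.mean())
    yc = y - y_mean
    ssx0 = float((E**2).sum())
    w = E.T @ yc
    nw = np.linalg.norm(w)
    if nw <= 0:
        raise ValueError("X carries no covariance with y")
    w = w / nw
    W_o = np.empty((p, n_ortho))
    T_o = np.empty((n, n_ortho))
    P_o = np.empty((p, n_ortho))
    r2x_orth = 0.0
    for k in range(n_ortho):
        t = E @ w
        tt = float(t @ t)
        pv = E.T @ t / tt
        w_o = pv - float(w @ pv) * w
        nwo = np.linalg.norm(w_o)
        if nwo <= 1e-10 * np.linalg.norm(pv):
            raise ValueError(
                f"n_ortho={n_ortho} too large: no orthogonal variation left "
                f"after {k} component(s)"
            )
        w_o /= nwo
        t_o = E @ w_o
        tto = float(t_o @ t_o)
        p_o = E.T @ t_o / tto
        _fix_sign(w_o, t_o, p_o)
        E -= np.outer(t_o, p_o)
        W_o[:, k], T_o[:, k], P_o[:, k] = w_o, t_o, p_o
        r2x_orth += tto * float(p_o @ p_o) / ssx0
    t = E @ w
    tt = float(t @ t)
    pv = E.T @ t / tt
    q = float(yc @ t) / tt
    r2x_pred = tt * float(pv @ pv) / ssx0
    resid = yc - q * t
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    return OPLSModel(
        w=w, t=t, p=pv, q=q, W_o=W_o, T_o=T_o, P_o=P_o, y_mean=y_mean,
        r2x_pred=r2x_pred, r2x_orth=r2x_orth, r2y=r2y,
    )


def predict_opls(model: OPLSModel, X_new, return_scores: bool = False):
    """Filter new data through the orthogonal components, then project onto
    the predictive component."""
    E = _as_array(X_new).copy()
    if E.shape[-1] != model.w.size:
        raise ValueError(
            f"column mismatch: got {E.shape[-1]}, model has {model.w.size}"
        )
    for k in range(model.n_ortho):
        t_o = E @ model.W_o[:, k]
        E -= np.outer(t_o, model.P_o[:, k])
    t = E @ model.w
    yhat = model.q * t + model.y_mean
    if return_scores:
        return yhat, t
    return yhat


# ---------------------------------------------------------------------------
# cross-validation

def q2_score(y: np.ndarray, yhat: np.ndarray) -> float:
    """``Q² = 1 - PRESS/SS`` with SS taken about the overall mean of y."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss = float(((y - y.mean()) ** 2).sum())
    if ss == 0:
        raise ValueError("y is constant; Q2 undefined")
    press = float(((y - yhat) ** 2).sum())
    return 1.0 - press / ss


def stratified_folds(y: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Deterministic class-stratified fold assignment.

    Samples are visited in a seeded random order and each is assigned to
    the fold currently holding the fewest members of its class (ties to
    the lowest fold index).  The construction depends only on the class
    partition, not on the label values, so relabeling the classes leaves
    the folds unchanged.
    """
    y = np.asarray(y)
    n = y.size
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    counts: dict[object, np.ndarray] = {}
    for i in order:
        key = y[i].item() if hasattr(y[i], "item") else y[i]
        if key not in counts:
            counts[key] = np.zeros(k_folds, dtype=int)
        f = int(np.argmin(counts[key]))
        fold_of[i] = f
        counts[key][f] += 1
    return fold_of


def cross_validated_q2(
    X,
    y,
    model_kind: str = "pls",
    n_comp: int = 1,
    k_folds: int = 10,
    seed: int = 0,
    scale_method: str = "unit_variance",
):
    """k-fold cross-validated Q² with the scaling refit inside each fold.

    ``X`` is the *unscaled* bucket matrix; for ``model_kind="pls"`` the
    parameter ``n_comp`` is the component count A, for ``"opls"`` it is
    the number of orthogonal components (one predictive component always).

    Returns ``(q2, yhat_oof)`` where ``yhat_oof`` holds the out-of-fold
    prediction for every sample.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    _check_two_classes(y)
    if model_kind not in ("pls", "opls"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    fold_of = stratified_folds(y, k_folds, seed)
    yhat = np.empty_like(y)
    for f in range(k_folds):
        test = fold_of == f
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError(
                "a training fold contains a single class; use fewer folds"
            )
        scaler = ScaledMatrix.fit(X[train], scale_method)
        Xte = scaler.transform(X[test])
        if model_kind == "pls":
            model = fit_pls(scaler.values, y[train], n_comp)
            yhat[test] = predict_pls(model, Xte)
        else:
            model = fit_opls(scaler.values, y[train], n_comp)
            yhat[test] = predict_opls(model, Xte)
    return q2_score(y, yhat), yhat


def autofit_components(
    X,
    y,
    k_folds: int = 10,
    seed: int = 0,
    scale_method: str = "unit_variance",
    a_max: int = 5,
    min_gain: float = 0.02,
) -> tuple[int, list[float]]:
    """Choose the PLS component count by cross-validated Q².

    Components are added while each one improves Q² by at least
    ``min_gain``, up to ``a_max``; the chosen count maximizes Q² over the
    accepted sequence.  Mirrors the common autofit heuristic of
    commercial chemometrics software.
    """
    stratified_folds(np.asarray(y), k_folds, seed)  # surface fold errors early
    q2s: list[float] = []
    best_a = 1
    for a in range(1, a_max + 1):
        try:
            q2, _ = cross_validated_q2(
                X, y, "pls", a, k_folds=k_folds, seed=seed, scale_method=scale_method
            )
        except ValueError:  # rank exhausted inside a fold
            break
        q2s.append(q2)
        if a > 1 and q2 - q2s[best_a - 1] < min_gain:
            break
        if q2 >= q2s[best_a - 1]:
            best_a = a
    if not q2s:
        raise ValueError("could not fit a single PLS component")
    return best_a, q2s
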