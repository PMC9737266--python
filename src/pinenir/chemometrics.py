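"""Latent-variable engines written from scratch: PCA with Hotelling's T2 and
Q-residual outlier statistics, PLS1 regression via NIPALS, and PLS-DA as
PLS2 on one-hot class indicators with an argmax assignment rule.

Conventions
-----------
* All models center internally and store the centering vectors, so callers
  pass raw (already spectrally preprocessed) matrices.
* PCA is computed by SVD of the centered matrix (numerically robust,
  identical subspace to the power-iteration form).
* PLS uses NIPALS with deflation; the regression vector for k components is
  ``b_k = W_k (P_k' W_k)^{-1} q_k`` so that prediction in the original
  (preprocessed) x-space is ``y_hat = y_mean + (x - x_mean)' b``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PCAModel", "fit_pca", "flag_outliers",
    "PLSModel", "fit_pls1", "predict_pls",
    "PLSDAModel", "fit_plsda", "predict_plsda",
    "model_to_json", "model_from_json",
]

DEFAULT_CLASS_ORDER: tuple[str, ...] = ("Aleppo", "Maritime", "Brutia")


# ---------------------------------------------------------------------------
# PCA + outlier statistics
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    n_pc: int
    loadings: np.ndarray            # (p, n_pc), orthonormal columns
    scores: np.ndarray              # (n, n_pc)
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray         # score variances lambda_a (ddof=1)
    residual_eigenvalues: np.ndarray
    T2: np.ndarray
    Q: np.ndarray
    T2_limit: float
    Q_limit: float
    conf_level: float


def fit_pca(X: np.ndarray, n_pc: int, conf_level: float = 0.99) -> PCAModel:
    """PCA of a column-centered matrix with T2/Q outlier statistics.

    ``X`` must be centered (column means ~ 0). Explained-variance
    percentages come from the squared singular values; Hotelling's
    T2_i = sum_a t_ia^2 / lambda_a over the retained components, and Q_i is
    the squared reconstruction residual. The T2 limit uses the F-scaling of
    Hotelling's statistic; the Q limit uses the Jackson-Mudholkar
    approximation from the discarded eigenvalues.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.max(np.abs(X.mean(axis=0))) > 1e-6 * max(1.0, np.abs(X).max()):
        raise ValueError("fit_pca expects a column-centered matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if n_pc < 1:
        raise ValueError("n_pc must be >= 1")
    if n_pc > rank:
        warnings.warn(f"n_pc={n_pc} exceeds rank {rank}; reduced", stacklevel=2)
        n_pc = rank
    total = float(np.sum(s ** 2))
    expl = 100.0 * s ** 2 / total
    lam = s ** 2 / (n - 1)

    scores = U[:, :n_pc] * s[:n_pc]
    T2 = np.sum(scores ** 2 / lam[:n_pc], axis=1)
    resid = X - scores @ Vt[:n_pc]
    Q = np.sum(resid ** 2, axis=1)

    a = n_pc
    if n - a > 0:
        T2_limit = a * (n - 1) / (n - a) * stats.f.ppf(conf_level, a, n - a)
    else:
        T2_limit = np.inf
    lam_resid = lam[n_pc:rank]
    Q_limit = _jackson_mudholkar_limit(lam_resid, conf_level)

    return PCAModel(
        n_pc=n_pc, loadings=Vt[:n_pc].T, scores=scores,
        explained_variance_pct=expl[:rank], eigenvalues=lam[:n_pc],
        residual_eigenvalues=lam_resid, T2=T2, Q=Q,
        T2_limit=float(T2_limit), Q_limit=float(Q_limit), conf_level=conf_level)


def _jackson_mudholkar_limit(lam_resid: np.ndarray, conf_level: float) -> float:
    th1 = float(np.sum(lam_resid))
    th2 = float(np.sum(lam_resid ** 2))
    th3 = float(np.sum(lam_resid ** 3))
    if th1 <= 0 or th2 <= 0:
        return 0.0
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if h0 <= 0:
        h0 = 1e-3  # degenerate spectrum of residual eigenvalues
    z = stats.norm.ppf(conf_level)
    term = (z * np.sqrt(2.0 * th2 * h0 ** 2) / th1
            + 1.0 + th2 * h0 * (h0 - 1.0) / th1 ** 2)
    if term <= 0:
        return 0.0
    return float(th1 * term ** (1.0 / h0))


def flag_outliers(m: PCAModel) -> np.ndarray:
    """Advisory per-spectrum flags: T2 or Q above its confidence limit."""
    return (m.T2 > m.T2_limit) | (m.Q > m.Q_limit)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class Provenance:
    """What a model was trained on: region combination, preprocessing label,
    target parameter / class order."""
    region_combo: tuple[str, ...] = ()
    preprocess: str = "none"
    parameter: str | None = None


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, n_lv) weights
    P: np.ndarray  # (p, n_lv) x-loadings
    q: np.ndarray  # (n_lv,) y-loadings
    b: np.ndarray  # (p,) regression vector in preprocessed x-space
    provenance: Provenance = field(default_factory=Provenance)

    def regression_vector(self, k: int | None = None) -> np.ndarray:
        """b for the first ``k`` latent variables (default: all)."""
        k = self.n_lv if k is None else k
        if not 0 <= k <= self.n_lv:
            raise ValueError(f"k={k} outside [0, {self.n_lv}]")
        if k == 0:
            return np.zeros(self.x_mean.size)
        Wk, Pk, qk = self.W[:, :k], self.P[:, :k], self.q[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS recursion on centered data; may stop early on a zero weight."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc)
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(scale, 1e-30) or not np.isfinite(nw):
            warnings.warn(
                f"NIPALS stopped after {a} latent variables "
                "(response orthogonal to X residual)", stacklevel=3)
            return W[:, :a], P[:, :a], q[:a]
        w /= nw
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - t * q_a
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    return W, P, q


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int,
             provenance: Provenance | None = None) -> PLSModel:
    """Fit a PLS1 regression with ``n_lv`` latent variables via NIPALS.

    Centering vectors are estimated from ``X``/``y`` and stored; prediction
    is ``y_mean + (x - x_mean)' b``. If the response becomes orthogonal to
    the deflated X before ``n_lv`` components, the model stops early with a
    warning and carries fewer LVs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if n_lv < 0:
        raise ValueError("n_lv must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    m = PLSModel(n_lv=W.shape[1], x_mean=x_mean, y_mean=y_mean,
                 W=W, P=P, q=q, b=np.zeros(X.shape[1]),
                 provenance=provenance or Provenance())
    m.b = m.regression_vector()
    return m


def predict_pls(m: PLSModel, X_new: np.ndarray, k: int | None = None) -> np.ndarray:
    """Predict responses for new rows; ``k`` truncates to the first k LVs."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model expects {m.x_mean.size}")
    b = m.b if k is None else m.regression_vector(k)
    return m.y_mean + (X_new - m.x_mean) @ b


# ---------------------------------------------------------------------------
# PLS2 / PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_lv: int
    class_labels: tuple[str, ...]
    x_mean: np.ndarray
    y_mean: np.ndarray              # (c,)
    W: np.ndarray                   # (p, n_lv)
    P: np.ndarray                   # (p, n_lv)
    Q: np.ndarray                   # (c, n_lv) y-loadings
    B: np.ndarray                   # (p, c) regression matrix
    provenance: Provenance = field(default_factory=Provenance)

    def regression_matrix(self, k: int | None = None) -> np.ndarray:
        k = self.n_lv if k is None else k
        if k == 0:
            return np.zeros((self.x_mean.size, self.y_mean.size))
        Wk, Pk, Qk = self.W[:, :k], self.P[:, :k], self.Q[:, :k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)


def _nipals_pls2(Xc: np.ndarray, Yc: np.ndarray, n_lv: int,
                 tol: float = 1e-10, max_iter: int = 500):
    n, p = Xc.shape
    c = Yc.shape[1]
    X, Y = Xc.copy(), Yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((c, n_lv))
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(Yc), 1e-30)
    for a in range(n_lv):
        # start u from the Y column with the largest remaining variance
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if np.linalg.norm(u) <= 1e-12 * scale:
            return W[:, :a], P[:, :a], Q[:, :a]
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * scale:
                return W[:, :a], P[:, :a], Q[:, :a]
            w /= nw
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = Y.T @ t / tt
        X = X - np.outer(t, p_a)
        Y = Y - np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a] = w, p_a, q_a
    return W, P, Q


def one_hot(labels, class_labels=DEFAULT_CLASS_ORDER) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    unseen = sorted(set(labels) - set(class_labels))
    if unseen:
        raise ValueError(f"labels not in class order {class_labels}: {unseen}")
    Y = np.zeros((labels.size, len(class_labels)))
    for j, c in enumerate(class_labels):
        Y[labels == c, j] = 1.0
    return Y


def fit_plsda(X: np.ndarray, labels, n_lv: int,
              class_labels: tuple[str, ...] = DEFAULT_CLASS_ORDER,
              provenance: Provenance | None = None) -> PLSDAModel:
    """PLS-DA: PLS2 on the one-hot indicator matrix over ``class_labels``.

    Requires at least two classes present in training. Class assignment is
    by argmax of the predicted indicator scores; ties break toward the
    earlier class in ``class_labels``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("PLS-DA needs at least two classes in training")
    Y = one_hot(labels, class_labels)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, P, Q = _nipals_pls2(X - x_mean, Y - y_mean, n_lv)
    m = PLSDAModel(n_lv=W.shape[1], class_labels=tuple(class_labels),
                   x_mean=x_mean, y_mean=y_mean, W=W, P=P, Q=Q,
                   B=np.zeros((X.shape[1], Y.shape[1])),
                   provenance=provenance or Provenance())
    m.B = m.regression_matrix()
    return m


def plsda_scores(m: PLSDAModel, X_new: np.ndarray, k: int | None = None) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model expects {m.x_mean.size}")
    B = m.B if k is None else m.regression_matrix(k)
    return m.y_mean + (X_new - m.x_mean) @ B


def predict_plsda(m: PLSDAModel, X_new: np.ndarray, k: int | None = None) -> np.ndarray:
    """Predicted class labels (argmax of indicator scores)."""
    scores = plsda_scores(m, X_new, k)
    idx = np.argmax(scores, axis=1)
    return np.asarray([m.class_labels[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# JSON serialization (single-document model exchange for the CLI)
# ---------------------------------------------------------------------------

def model_to_json(m: PLSModel | PLSDAModel, preprocessor=None) -> str:
    doc: dict = {"provenance": {
        "region_combo": list(m.provenance.region_combo),
        "preprocess": m.provenance.preprocess,
        "parameter": m.provenance.parameter,
    }}
    if preprocessor is not None:
        doc["preprocess_fit"] = {
            "block_boundaries": list(preprocessor.block_boundaries),
            "column_means": None if preprocessor.column_means is None
            else preprocessor.column_means.tolist(),
            "column_sds": None if preprocessor.column_sds is None
            else preprocessor.column_sds.tolist(),
        }
    if isinstance(m, PLSDAModel):
        doc["kind"] = "plsda"
        doc.update(n_lv=m.n_lv, class_labels=list(m.class_labels),
                   x_mean=m.x_mean.tolist(), y_mean=m.y_mean.tolist(),
                   W=m.W.tolist(), P=m.P.tolist(), Q=m.Q.tolist(), B=m.B.tolist())
    else:
        doc["kind"] = "pls1"
        doc.update(n_lv=m.n_lv, x_mean=m.x_mean.tolist(), y_mean=m.y_mean,
                   W=m.W.tolist(), P=m.P.tolist(), q=m.q.tolist(), b=m.b.tolist())
    return json.dumps(doc)


def model_from_json(text: str) -> PLSModel | PLSDAModel:
    doc = json.loads(text)
    prov = Provenance(tuple(doc["provenance"]["region_combo"]),
                      doc["provenance"]["preprocess"],
                      doc["provenance"]["parameter"])
    if doc["kind"] == "plsda":
        return PLSDAModel(
            n_lv=doc["n_lv"], class_labels=tuple(doc["class_labels"]),
            x_mean=np.asarray(doc["x_mean"]), y_mean=np.asarray(doc["y_mean"]),
            W=np.asarray(doc["W"]), P=np.asarray(doc["P"]),
            Q=np.asarray(doc["Q"]), B=np.asarray(doc["B"]), provenance=prov)
    return PLSModel(
        n_lv=doc["n_lv"], x_mean=np.asarray(doc["x_mean"]), y_mean=doc["y_mean"],
        W=np.asarray(doc["W"]), P=np.asarray(doc["P"]),
        q=np.asarray(doc["q"]), b=np.asarray(doc["b"]), provenance=prov)
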