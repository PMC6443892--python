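"""Sparse partial least squares discriminant analysis (sPLS-DA).

A NIPALS-style PLS2 on an autoscaled predictor matrix X against a centered
dummy-coded class response Y, with per-component soft-thresholding of the
X-loading weights so that only the ``keep`` largest-magnitude variables
survive in each component.  Used to rank morphological variables by their
stress response and transpiration variables by phenotype-group membership.

Conventions: X is column-autoscaled (mean 0, sd 1) before fitting; constant
columns are dropped with a warning; each component's sign is fixed so its
largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplsdaModel:
    n_components: int
    variables: list[str]
    classes: list[str]
    loadings: np.ndarray          # (p, K) sparse X-weights, unit norm
    scores: np.ndarray            # (n, K) sample scores, mutually orthogonal
    x_loadings: np.ndarray        # (p, K) regression loadings used for deflation
    y_loadings: np.ndarray        # (n_classes, K)
    kept: list[np.ndarray]        # per-component indices of retained variables
    explained_variance: np.ndarray  # (K,) fraction of total X variance
    x_mean: np.ndarray = field(default=None, repr=False)
    x_scale: np.ndarray = field(default=None, repr=False)


def _dummy_code(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(map(str, labels)))
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.array([str(l) == c for l in labels]), j] = 1.0
    return Y - Y.mean(axis=0), classes


def _soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|w| entries, shrinking the rest to zero."""
    p = w.size
    if keep >= p:
        return w
    lam = np.sort(np.abs(w))[p - keep - 1]
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def fit_splsda(
    X: np.ndarray | pd.DataFrame,
    class_labels,
    n_components: int = 5,
    keep_per_component: int | list[int] | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X : (n, p) matrix of predictors (autoscaled internally).
    class_labels : n class labels (≥ 2 classes).
    n_components : number of latent components (reduced with a warning when
        it exceeds the rank of X).
    keep_per_component : number of variables retained per component; ``None``
        keeps all p (dense PLS-DA).
    """
    if isinstance(X, pd.DataFrame):
        variables = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        variables = [f"x{i}" for i in range(Xm.shape[1])]
    labels = np.asarray(class_labels)
    if len(set(map(str, labels))) < 2:
        raise ValueError("need at least 2 classes")
    n, p = Xm.shape

    mean = Xm.mean(axis=0)
    sd = Xm.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant column(s): "
            f"{[v for v, c in zip(variables, const) if c]}",
            stacklevel=2,
        )
        keep_cols = ~const
        Xm, mean, sd = Xm[:, keep_cols], mean[keep_cols], sd[keep_cols]
        variables = [v for v, c in zip(variables, const) if not c]
        p = Xm.shape[1]
    Xc = (Xm - mean) / sd

    rank = int(np.linalg.matrix_rank(Xc))
    K = n_components
    if K > rank:
        warnings.warn(f"n_components reduced from {K} to rank(X) = {rank}", stacklevel=2)
        K = rank

    Y, classes = _dummy_code(labels)
    if keep_per_component is None:
        keeps = [p] * K
    elif np.isscalar(keep_per_component):
        keeps = [min(int(keep_per_component), p)] * K
    else:
        keeps = [min(int(k), p) for k in keep_per_component]
        keeps += [p] * (K - len(keeps))

    total_var = float((Xc**2).sum())
    Xd, Yd = Xc.copy(), Y.copy()
    W = np.zeros((p, K))
    T = np.zeros((n, K))
    P = np.zeros((p, K))
    Q = np.zeros((Y.shape[1], K))
    kept: list[np.ndarray] = []
    expl = np.zeros(K)

    for k in range(K):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if not np.any(u):
            u = Yd[:, 0] + 1e-12
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            w_new = _soft_threshold(w_new, keeps[k])
            nrm = np.linalg.norm(w_new)
            if nrm == 0:  # all weights thresholded away; fall back to dense
                w_new = Xd.T @ u
                nrm = np.linalg.norm(w_new)
                if nrm == 0:
                    break
            w_new /= nrm
            t = Xd @ w_new
            tt = t @ t
            if tt == 0:
                w = w_new
                break
            q = Yd.T @ t / tt
            u_new = Yd @ q
            qq = q @ q
            if qq > 0:
                u_new = u_new / qq
            if np.linalg.norm(w_new - w) < tol:
                w, u = w_new, u_new
                break
            w, u = w_new, u_new
        # fix sign: largest-|loading| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            K = k
            break
        p_load = Xd.T @ t / tt
        q = Yd.T @ t / tt
        W[:, k], T[:, k], P[:, k], Q[:, k] = w, t, p_load, q
        kept.append(np.nonzero(w)[0])
        expl[k] = tt * float(p_load @ p_load) / total_var
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)

    return SplsdaModel(
        n_components=K,
        variables=variables,
        classes=classes,
        loadings=W[:, :K],
        scores=T[:, :K],
        x_loadings=P[:, :K],
        y_loadings=Q[:, :K],
        kept=kept[:K],
        explained_variance=expl[:K],
        x_mean=mean,
        x_scale=sd,
    )


def variable_importance(model: SplsdaModel) -> pd.Series:
    """Importance per variable: max over components of |loading| weighted by
    that component's share of explained X variance."""
    ev = model.explained_variance
    share = ev / ev.sum() if ev.sum() > 0 else np.full_like(ev, 1.0 / max(ev.size, 1))
    imp = np.max(np.abs(model.loadings) * share[np.newaxis, :], axis=1)
    return pd.Series(imp, index=model.variables, name="importance")


def rank_variables(
    model: SplsdaModel,
    raw_data: pd.DataFrame,
    class_labels,
    positive_class: str,
    top: int | None = 10,
) -> pd.DataFrame:
    """Rank variables by model importance, signed by their direction of change.

    The sign is the sign of (median in ``positive_class`` − median in the
    other class) of the *raw*, unscaled variable, labelling each selected
    variable as increased or decreased in the positive class.
    """
    imp = variable_importance(model).sort_values(ascending=False)
    labels = np.asarray([str(l) for l in class_labels])
    pos = labels == str(positive_class)
    rows = []
    for var in imp.index:
        col = raw_data[var].to_numpy(dtype=float)
        delta = float(np.nanmedian(col[pos]) - np.nanmedian(col[~pos]))
        rows.append(
            {
                "variable": var,
                "importance": float(imp[var]),
                "delta_median": delta,
                "direction": "increased" if delta > 0 else ("decreased" if delta < 0 else "unchanged"),
            }
        )
    out = pd.DataFrame(rows)
    return out.head(top) if top is not None else out
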