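"""Partial least squares regression of outcome on whole-brain voxel-wise
binding, variable-importance-in-projection (VIP) maps, and leave-one-out
cross-validated outcome prediction.

PLS1 (univariate y) is fitted by NIPALS on column-centered X and centered y.
Columns are centered but, by default, **not** variance-scaled: BP maps share
units across voxels, and VIP values depend on this choice (scaling sits
behind a flag). With as many components as the rank of X, PLS reproduces
ordinary least squares on the training set; with "a few" components it
regularizes the n-subjects << n-voxels problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    x_weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    x_scores: np.ndarray  # (n, A)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    explained_y_variance: np.ndarray  # (A,) fractions

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the (centered, scaled) X scale."""
        W, P, q = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.coefficients + self.y_mean


def pls1_fit(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = False
) -> PLSModel:
    """NIPALS PLS1 with deflation of X and y per component. Deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_subjects, n_voxels) matching y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    rank_cap = min(n - 1, p)
    if n_components > rank_cap:
        raise ValueError(
            f"n_components={n_components} exceeds the rank cap {rank_cap}"
        )
    ss_y_total = float(yc @ yc)
    if ss_y_total == 0:
        raise ValueError("y has zero variance")
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"rank exhausted at component {a + 1}")
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        p_load = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd -= q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
        ssy[a] = q_a**2 * tt
    return PLSModel(
        n_components=n_components,
        x_weights=W, x_loadings=P, y_loadings=q, x_scores=T,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        explained_y_variance=ssy / ss_y_total,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a[SSY_a (w_ja/||w_a||)^2] / sum_a SSY_a ).

    The mean of squared VIPs over predictors is 1 by construction; VIP > 1
    marks a variable as important.
    """
    ssy = model.explained_y_variance
    if ssy.sum() <= 0:
        raise ValueError("model explains no y variance")
    W = model.x_weights
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    return np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())


def _inner_loo_rmse(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """RMSE of leave-one-out prediction for each component count."""
    n = len(y)
    cap = min(max_components, n - 2, X.shape[1])
    errs = np.zeros((cap, n))
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, cap + 1):
            model = pls1_fit(X[keep], y[keep], a)
            errs[a - 1, i] = model.predict(X[i : i + 1])[0] - y[i]
    return np.sqrt((errs**2).mean(axis=1))


def loo_predict(
    X: np.ndarray, y: np.ndarray, max_components: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out cross-validated predictions.

    For each held-out subject the model is refitted on the rest, with the
    component count chosen by an inner leave-one-out RMSE criterion (capped
    at ``max_components``). Returns (observed, predicted); the held-out
    subject never contributes to its own fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out")
    preds = np.zeros(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        if np.allclose(yi, yi[0]):
            preds[i] = yi[0]
            continue
        rmse = _inner_loo_rmse(Xi, yi, max_components)
        a_best = int(np.argmin(rmse)) + 1 if len(rmse) else 1
        model = pls1_fit(Xi, yi, a_best)
        preds[i] = model.predict(X[i : i + 1])[0]
    return y.copy(), preds


@dataclass(frozen=True)
class VipMap:
    vip: np.ndarray
    important_mask: np.ndarray  # VIP strictly > 1


def vip_map(vip_vector: np.ndarray, brain_mask: np.ndarray) -> VipMap:
    """Reshape a per-voxel VIP vector into a 3D map over the brain mask and
    flag important voxels (VIP > 1, strict)."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    vip_vector = np.asarray(vip_vector, dtype=float)
    if vip_vector.shape != (int(brain_mask.sum()),):
        raise ValueError("VIP vector length does not match the mask size")
    vol = np.full(brain_mask.shape, np.nan)
    vol[brain_mask] = vip_vector
    important = np.zeros(brain_mask.shape, dtype=bool)
    important[brain_mask] = vip_vector > 1.0
    return VipMap(vip=vol, important_mask=important)


def map_to_vector(vol: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Inverse of ``vip_map``: pull the in-mask values back into a vector."""
    return np.asarray(vol)[np.asarray(brain_mask, dtype=bool)]
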