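"""Missing-value-tolerant principal component analysis.

Single-cell qPCR matrices routinely contain failed reactions, so the
default PCA is an EM-fitted probabilistic PCA (``ppca_em``) that treats
masked entries as unobserved: the model is ``x = W t + mu + eps`` with
isotropic noise, and the E-step conditions each cell's latent score on
its observed genes only.  On complete data the converged subspace
coincides with the classical eigendecomposition; on masked data the
model's reconstruction of the hidden entries is used for imputation-type
diagnostics.  A ``classical_mean_impute`` method (per-gene mean fill +
eigendecomposition) is kept as a cross-check.

Input is expected on a log2 scale (see :func:`icmcoord.io.log2_transform`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix
from .errors import ConvergenceError, InputError


@dataclass
class PCAResult:
    """Per-cell component scores and per-component explained variance."""

    scores: np.ndarray            # cells x components
    loadings: np.ndarray          # genes x components (orthonormal columns)
    explained_fraction: np.ndarray
    n_components: int
    method: str
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_variance: float = 0.0
    n_iterations: int = 0

    def reconstruction(self) -> np.ndarray:
        """Rank-``n_components`` reconstruction of the data (model mean
        plus scores @ loadings.T); used to fill masked entries."""
        return self.mean[None, :] + self.scores @ self.loadings.T


def _order_and_sign(scores: np.ndarray, loadings: np.ndarray):
    """Order components by decreasing score variance; fix each
    component's sign so its largest-|loading| gene loads positively."""
    var = scores.var(axis=0)
    order = np.argsort(var)[::-1]
    scores = scores[:, order]
    loadings = loadings[:, order]
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return scores, loadings, var[order]


def _total_observed_variance(x: np.ndarray) -> float:
    """Sum of per-gene variances over observed entries (NaN-aware)."""
    with np.errstate(invalid="ignore"):
        v = np.nanvar(x, axis=0)
    return float(np.nansum(v))


def _classical(x: np.ndarray, n_components: int):
    """Mean-impute masked entries per gene, center, eigendecompose."""
    col_mean = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), col_mean[None, :], x)
    centered = filled - col_mean[None, :]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    ev = (s**2) / (x.shape[0])
    total = ev.sum()
    explained = ev[:n_components] / total if total > 0 else np.zeros(n_components)
    return scores, loadings, explained, col_mean


def _ppca_em(
    x: np.ndarray,
    n_components: int,
    seed: int,
    tol: float,
    max_iter: int,
):
    """EM for probabilistic PCA with missing entries.

    Returns (scores, loadings, mean, sigma2, history).  Convergence is
    declared on the model-relevant quantities: the sine of the largest
    principal angle between successive loading subspaces plus the
    relative change of the noise variance must fall below ``tol`` (the
    likelihood is flat under within-subspace rotations of W, so raw
    parameter change is not a usable criterion).
    """
    n, d = x.shape
    k = n_components
    obs = ~np.isnan(x)
    rng = np.random.default_rng(seed)

    mu = np.nanmean(x, axis=0)
    w = rng.standard_normal((d, k)) * 0.01
    sigma2 = float(np.nanvar(x))
    if sigma2 == 0.0:
        sigma2 = 1e-12

    xc = np.where(obs, x - mu[None, :], 0.0)
    complete_rows = obs.all(axis=1)
    history: list[float] = []
    n_obs_total = int(obs.sum())

    et = np.zeros((n, k))
    ett = np.zeros((n, k, k))

    for it in range(1, max_iter + 1):
        eye = np.eye(k)
        # E-step -----------------------------------------------------------
        if complete_rows.any():
            m_full = sigma2 * eye + w.T @ w
            m_inv = np.linalg.inv(m_full)
            rows = np.flatnonzero(complete_rows)
            et[rows] = xc[rows] @ w @ m_inv
            cov = sigma2 * m_inv
            for i in rows:
                ett[i] = cov + np.outer(et[i], et[i])
        for i in np.flatnonzero(~complete_rows):
            o = obs[i]
            wo = w[o]
            m_i = sigma2 * eye + wo.T @ wo
            m_inv = np.linalg.inv(m_i)
            et[i] = m_inv @ wo.T @ xc[i, o]
            ett[i] = sigma2 * m_inv + np.outer(et[i], et[i])
        # M-step -----------------------------------------------------------
        new_w = np.empty_like(w)
        for j in range(d):
            rows = obs[:, j]
            a = ett[rows].sum(axis=0)
            b = xc[rows, j] @ et[rows]
            new_w[j] = np.linalg.solve(a, b)
        # mean update from residuals of observed entries
        recon = et @ new_w.T
        resid = np.where(obs, (x - mu[None, :]) - recon, 0.0)
        mu = mu + resid.sum(axis=0) / obs.sum(axis=0)
        xc = np.where(obs, x - mu[None, :], 0.0)
        # noise variance
        sq = 0.0
        for j in range(d):
            rows = obs[:, j]
            wj = new_w[j]
            sq += float(
                (xc[rows, j] ** 2).sum()
                - 2.0 * (xc[rows, j] @ et[rows]) @ wj
                + np.einsum("i,nij,j->", wj, ett[rows], wj)
            )
        new_sigma2 = max(sq / n_obs_total, 1e-15)

        change = abs(new_sigma2 - sigma2) / max(sigma2, 1e-15)
        q_old, _ = np.linalg.qr(w)
        q_new, _ = np.linalg.qr(new_w)
        cosines = np.clip(np.linalg.svd(q_old.T @ q_new, compute_uv=False), 0.0, 1.0)
        change = max(change, float(np.sqrt(1.0 - cosines.min() ** 2)))
        w, sigma2 = new_w, new_sigma2
        history.append(sigma2)
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"ppca_em did not converge in {max_iter} iterations "
            f"(last relative change {change:.2e})",
            history=history,
        )
    # final E-step with converged parameters
    eye = np.eye(k)
    for i in range(n):
        o = obs[i]
        wo = w[o]
        m_inv = np.linalg.inv(sigma2 * eye + wo.T @ wo)
        et[i] = m_inv @ wo.T @ xc[i, o]
    # rotate to an orthonormal loading basis
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    scores = et @ vt.T * s[None, :]
    return scores, u, mu, sigma2, history


def fit_pca(
    m: ExpressionMatrix,
    n_components: int = 2,
    method: str = "ppca_em",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> PCAResult:
    """Fit a PCA on a (log-scale) expression matrix.

    ``ppca_em`` handles masked entries through the probabilistic model;
    ``classical_mean_impute`` replaces them with per-gene means before an
    exact eigendecomposition.  Components are ordered by decreasing
    explained-variance fraction; signs are fixed deterministically.
    Raises :class:`ConvergenceError` (with the iteration trace) if EM
    does not converge.
    """
    if method not in ("ppca_em", "classical_mean_impute"):
        raise InputError(f"unknown PCA method {method!r}")
    x = m.nan_values()
    n, d = x.shape
    if n < n_components + 1 or d < n_components + 1:
        raise InputError(
            f"need at least {n_components + 1} cells and genes for "
            f"{n_components} components"
        )
    if np.isnan(x).all(axis=0).any():
        bad = [m.gene_ids[j] for j in np.flatnonzero(np.isnan(x).all(axis=0))]
        raise InputError(f"genes with no observed values: {bad}")
    total_var = _total_observed_variance(x)

    if method == "classical_mean_impute":
        scores, loadings, explained, mu = _classical(x, n_components)
        scores, loadings, _ = _order_and_sign(scores, loadings)
        return PCAResult(
            scores=scores, loadings=loadings,
            explained_fraction=np.sort(explained)[::-1],
            n_components=n_components, method=method,
            cell_ids=list(m.cell_ids), gene_ids=list(m.gene_ids),
            mean=mu,
        )

    scores, loadings, mu, sigma2, history = _ppca_em(
        x, n_components, seed=seed, tol=tol, max_iter=max_iter
    )
    scores, loadings, var = _order_and_sign(scores, loadings)
    explained = var / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(
        scores=scores, loadings=loadings,
        explained_fraction=explained,
        n_components=n_components, method=method,
        cell_ids=list(m.cell_ids), gene_ids=list(m.gene_ids),
        mean=mu, noise_variance=sigma2, n_iterations=len(history),
    )


def principal_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle (radians) between the column spaces of two
    loading matrices."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.arccos(s.min()))
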