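"""Negative-binomial numerics shared across the package.

The NB distribution for gene j is written in exponential-family form for the
size-factor-adjusted expression mu_ij = Y_ij / s_i:

    p(mu | theta) = h(mu) exp(mu * theta - A(theta)),
    A(theta) = -phi * log(1 - e^theta),   theta < 0,

so the mean function is m(theta) = A'(theta) = phi * e^theta / (1 - e^theta)
and the variance is A''(theta) = m + m^2 / phi. The canonical
parameterization makes the log-likelihood concave in theta, which the
alternating factor-model fit exploits; the constraint theta < 0 is enforced
by the likelihood barrier (log(1 - e^theta) -> -inf as theta -> 0) plus
explicit mean clipping to [MEAN_MIN, MEAN_MAX].

All solvers here are batched with numpy across genes (or observations):
one Newton step solves thousands of small q x q systems at once, with
per-unit step halving to keep every unit's likelihood monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "nb_mean_from_theta",
    "theta_from_mean",
    "nb_variance",
    "nb_loglik",
    "nb_logpmf",
    "loglik_elements",
    "deviance_residuals",
    "dispersion_moments",
    "dispersion_mle",
    "fit_nb_glm_canonical",
    "fit_rows_canonical",
    "fit_nb_glm_log_link",
    "fit_rows_log_link",
]

MEAN_MIN = 1e-8
MEAN_MAX = 1e6
_MAX_HALVINGS = 30


def nb_mean_from_theta(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """m(theta) = phi * e^theta / (1 - e^theta), for theta < 0."""
    return phi / np.expm1(-theta)


def theta_from_mean(m: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Inverse link theta = log(m / (m + phi)) with the mean clipped positive."""
    m = np.clip(m, MEAN_MIN, MEAN_MAX)
    return -np.log1p(phi / m)


def nb_variance(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """A''(theta) = m + m^2/phi."""
    m = nb_mean_from_theta(theta, phi)
    return m + m * m / phi


def loglik_elements(yadj: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Elementwise yadj*theta + phi*log(1 - e^theta); -inf where theta >= 0.

    Drops the base-measure term h (independent of theta), so differences of
    this quantity are exact log-likelihood-ratio contributions.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.full(np.broadcast(yadj, theta).shape, -np.inf)
    ok = theta < 0
    with np.errstate(invalid="ignore"):
        vals = yadj * theta + phi * np.log1p(-np.exp(theta))
    out[ok] = np.broadcast_to(vals, out.shape)[ok]
    return out


def nb_loglik(Y: np.ndarray, Theta: np.ndarray, phi: np.ndarray, s: np.ndarray) -> float:
    """Total NB log-likelihood of adjusted expression Y/s at natural parameters Theta.

    Includes the base measure h(mu) = C(mu + phi - 1, mu) through its gamma-
    function extension, so at s = 1 this is the exact log pmf summed over
    entries.
    """
    Y = np.asarray(Y, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(Theta >= 0):
        raise ValueError("natural parameters must satisfy theta < 0")
    if np.any(phi <= 0) or np.any(s <= 0):
        raise ValueError("phi and size factors must be strictly positive")
    yadj = Y / s[:, None]
    core = loglik_elements(yadj, Theta, phi[None, :])
    base = gammaln(yadj + phi[None, :]) - gammaln(phi[None, :]) - gammaln(yadj + 1.0)
    total = float(np.sum(core + base))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite NB log-likelihood")
    return total


def nb_logpmf(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Count-scale NB log pmf with mean mu and dispersion phi (variance mu + mu^2/phi)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), MEAN_MIN, None)
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + y * (np.log(mu) - np.log(mu + phi))
        + phi * (np.log(phi) - np.log(mu + phi))
    )


def deviance_residuals(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Signed square-root NB deviance residuals of counts Y under fitted means mu."""
    Y = np.asarray(Y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), MEAN_MIN, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * (np.log(Y) - np.log(mu)), 0.0)
    term2 = (Y + phi) * (np.log(Y + phi) - np.log(mu + phi))
    dev = 2.0 * (term1 - term2)
    dev = np.clip(dev, 0.0, None)  # guard tiny negative rounding
    return np.sign(Y - mu) * np.sqrt(dev)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def dispersion_moments(
    yadj: np.ndarray, phi_bounds: tuple[float, float] = (0.01, 100.0)
) -> np.ndarray:
    """Method-of-moments dispersion phi = mean^2 / (var - mean), per gene, clamped.

    Genes with variance <= mean (no detectable overdispersion) are clamped to
    the upper bound.
    """
    lo, hi = phi_bounds
    mbar = yadj.mean(axis=0)
    v = yadj.var(axis=0, ddof=1) if yadj.shape[0] > 1 else np.zeros(yadj.shape[1])
    excess = v - mbar
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(excess > 0, mbar**2 / excess, hi)
    phi = np.where(np.isfinite(phi), phi, hi)
    return np.clip(phi, lo, hi)


def dispersion_mle(
    Y: np.ndarray,
    mu: np.ndarray,
    phi_bounds: tuple[float, float] = (0.01, 100.0),
    n_iter: int = 30,
) -> np.ndarray:
    """Per-gene NB dispersion MLE holding the fitted count-scale means fixed.

    Solves d loglik / d phi = 0 by vectorized bisection on log(phi); genes
    whose score is one-signed over the bracket sit at the corresponding bound.
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), MEAN_MIN, None)
    lo, hi = phi_bounds

    def score(phi_row: np.ndarray) -> np.ndarray:
        ph = phi_row[None, :]
        t = (
            digamma(Y + ph)
            - digamma(ph)
            + np.log(ph)
            + 1.0
            - np.log(ph + mu)
            - (Y + ph) / (ph + mu)
        )
        return t.sum(axis=0)

    p = Y.shape[1]
    lo_v = np.full(p, np.log(lo))
    hi_v = np.full(p, np.log(hi))
    s_lo = score(np.exp(lo_v))
    s_hi = score(np.exp(hi_v))
    at_lo = s_lo <= 0
    at_hi = s_hi >= 0
    for _ in range(n_iter):
        mid = 0.5 * (lo_v + hi_v)
        s_mid = score(np.exp(mid))
        go_up = s_mid > 0
        lo_v = np.where(go_up, mid, lo_v)
        hi_v = np.where(go_up, hi_v, mid)
    phi = np.exp(0.5 * (lo_v + hi_v))
    phi[at_lo] = lo
    phi[at_hi] = hi
    return phi


# ---------------------------------------------------------------------------
# batched canonical-link solvers (factor model blocks)
# ---------------------------------------------------------------------------


@dataclass
class BlockFitResult:
    coef: np.ndarray
    loglik: float
    converged: np.ndarray


def _theta_bounds(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return theta_from_mean(MEAN_MIN, phi), theta_from_mean(MEAN_MAX, phi)


def fit_nb_glm_canonical(
    yadj: np.ndarray,
    Z: np.ndarray,
    phi: np.ndarray,
    coef_init: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-10,
) -> BlockFitResult:
    """Per-gene canonical NB regression theta_j = offset + Z @ b_j, batched over genes.

    Parameters
    ----------
    yadj : (n, p) size-factor-adjusted counts.
    Z : (n, q) shared design.
    phi : (p,) dispersions (fixed).
    Returns coefficients (p, q); likelihood is monotone per gene via step halving.
    """
    n, p = yadj.shape
    q = Z.shape[1]
    phi_row = phi[None, :]
    off = 0.0 if offset is None else offset
    m0 = np.clip(yadj.mean(axis=0), 0.05, None)
    C0 = np.zeros((p, q))
    C0[:, 0] = theta_from_mean(m0, phi) if offset is None else 0.0
    lo, hi = _theta_bounds(phi)
    if coef_init is None:
        C = C0
    else:
        # fall back per gene to the safe intercept start when the warm start
        # lands in a worse (e.g. boundary-saturated) region
        C = coef_init.copy()
        ll_warm = loglik_elements(
            yadj, np.clip(off + Z @ C.T, lo[None, :], hi[None, :]), phi_row
        ).sum(axis=0)
        ll_safe = loglik_elements(
            yadj, np.clip(off + Z @ C0.T, lo[None, :], hi[None, :]), phi_row
        ).sum(axis=0)
        bad = ~(ll_warm >= ll_safe)
        C[bad] = C0[bad]
    Theta = np.clip(off + Z @ C.T, lo[None, :], hi[None, :])
    ll = loglik_elements(yadj, Theta, phi_row).sum(axis=0)
    converged = np.zeros(p, dtype=bool)
    ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(n, q * q)
    for _ in range(max_iter):
        M = nb_mean_from_theta(Theta, phi_row)
        V = M + M * M / phi_row
        G = Z.T @ (yadj - M)  # (q, p)
        H = (V.T @ ZZ).reshape(p, q, q)
        H += np.eye(q)[None, :, :] * (
            ridge + 1e-8 * (1.0 + np.trace(H, axis1=1, axis2=2))[:, None, None]
        )
        try:
            step = np.linalg.solve(H, G.T[:, :, None])[:, :, 0]  # (p, q)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(
                H + 1e-6 * np.eye(q)[None, :, :], G.T[:, :, None]
            )[:, :, 0]
        scale = np.ones(p)
        active = np.arange(p)
        for _ in range(_MAX_HALVINGS):
            C_cand = C[active] + scale[active, None] * step[active]
            off_a = off if np.isscalar(off) else off[:, active]
            cand = loglik_elements(
                yadj[:, active], off_a + Z @ C_cand.T, phi_row[:, active]
            ).sum(axis=0)
            good = cand >= ll[active] - 1e-12
            active = active[~good]
            if active.size == 0:
                break
            scale[active] *= 0.5
        if active.size:
            scale[active] = 0.0
        C = C + scale[:, None] * step
        Theta = np.clip(off + Z @ C.T, lo[None, :], hi[None, :])
        prev = ll
        ll = loglik_elements(yadj, Theta, phi_row).sum(axis=0)
        rel = np.abs(ll - prev) / (np.abs(prev) + 1.0)
        converged = rel < tol
        if converged.all():
            break
    return BlockFitResult(coef=C, loglik=float(ll.sum()), converged=converged)


def fit_rows_canonical(
    yadj: np.ndarray,
    Gamma: np.ndarray,
    phi: np.ndarray,
    U: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> BlockFitResult:
    """Per-observation update of latent scores: theta_i = offset_i + Gamma @ u_i.

    Symmetric counterpart of :func:`fit_nb_glm_canonical`, batched over rows.
    """
    n, p = yadj.shape
    r = Gamma.shape[1]
    phi_row = phi[None, :]
    lo, hi = _theta_bounds(phi)
    C = U.copy()
    ll_warm = loglik_elements(
        yadj, np.clip(offset + C @ Gamma.T, lo[None, :], hi[None, :]), phi_row
    ).sum(axis=1)
    ll_safe = loglik_elements(
        yadj, np.clip(offset, lo[None, :], hi[None, :]), phi_row
    ).sum(axis=1)
    bad = ~(ll_warm >= ll_safe)
    C[bad] = 0.0
    Theta = np.clip(offset + C @ Gamma.T, lo[None, :], hi[None, :])
    ll = loglik_elements(yadj, Theta, phi_row).sum(axis=1)
    converged = np.zeros(n, dtype=bool)
    GG = (Gamma[:, :, None] * Gamma[:, None, :]).reshape(p, r * r)
    for _ in range(max_iter):
        M = nb_mean_from_theta(Theta, phi_row)
        V = M + M * M / phi_row
        G = (yadj - M) @ Gamma  # (n, r)
        H = (V @ GG).reshape(n, r, r)
        H += np.eye(r)[None, :, :] * (
            1e-8 * (1.0 + np.trace(H, axis1=1, axis2=2))[:, None, None]
        )
        step = np.linalg.solve(H, G[:, :, None])[:, :, 0]
        scale = np.ones(n)
        active = np.arange(n)
        for _ in range(_MAX_HALVINGS):
            C_cand = C[active] + scale[active, None] * step[active]
            cand = loglik_elements(
                yadj[active], offset[active] + C_cand @ Gamma.T, phi_row
            ).sum(axis=1)
            good = cand >= ll[active] - 1e-12
            active = active[~good]
            if active.size == 0:
                break
            scale[active] *= 0.5
        if active.size:
            scale[active] = 0.0
        C = C + scale[:, None] * step
        Theta = np.clip(offset + C @ Gamma.T, lo[None, :], hi[None, :])
        prev = ll
        ll = loglik_elements(yadj, Theta, phi_row).sum(axis=1)
        rel = np.abs(ll - prev) / (np.abs(prev) + 1.0)
        converged = rel < tol
        if converged.all():
            break
    return BlockFitResult(coef=C, loglik=float(ll.sum()), converged=converged)


# ---------------------------------------------------------------------------
# batched log-link NB GLM (outcome models and factor-model blocks)
# ---------------------------------------------------------------------------

_ETA_LO = float(np.log(MEAN_MIN))
_ETA_HI = float(np.log(MEAN_MAX))


def _loglink_ll(Y: np.ndarray, mu: np.ndarray, phi_row: np.ndarray, axis: int = 0) -> np.ndarray:
    return (Y * (np.log(mu) - np.log(mu + phi_row)) - phi_row * np.log(mu + phi_row)).sum(
        axis=axis
    )


def fit_nb_glm_log_link(
    Y: np.ndarray,
    Z: np.ndarray,
    phi: np.ndarray,
    log_s: np.ndarray,
    coef_init: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> BlockFitResult:
    """Per-gene NB regression with log link and size-factor offset, batched.

    Model: Y_ij ~ NB(mean = exp(z_i @ b_j + log s_i), dispersion phi_j).
    Fisher scoring with per-gene step halving; an optional ridge penalty
    stabilizes separated/degenerate genes. A provided warm start falls back
    per gene to the safe intercept-only start when it is worse.
    """
    n, p = Y.shape
    q = Z.shape[1]
    Y = np.asarray(Y, dtype=float)
    phi_row = phi[None, :]
    off = log_s[:, None]
    B0 = np.zeros((p, q))
    B0[:, 0] = np.log(np.clip(Y.mean(axis=0), 0.05, None)) - np.mean(log_s)
    if coef_init is None:
        B = B0
    else:
        B = coef_init.copy()
        ll_warm = _loglink_ll(Y, np.exp(np.clip(off + Z @ B.T, _ETA_LO, _ETA_HI)), phi_row)
        ll_safe = _loglink_ll(Y, np.exp(np.clip(off + Z @ B0.T, _ETA_LO, _ETA_HI)), phi_row)
        bad = ~(ll_warm >= ll_safe)
        B[bad] = B0[bad]
    eta = np.clip(off + Z @ B.T, _ETA_LO, _ETA_HI)
    mu = np.exp(eta)
    ll = _loglink_ll(Y, mu, phi_row)
    converged = np.zeros(p, dtype=bool)
    eye = np.eye(q)[None, :, :]
    ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(n, q * q)
    for _ in range(max_iter):
        w = mu / (1.0 + mu / phi_row)  # Fisher weights
        G = Z.T @ ((Y - mu) / (1.0 + mu / phi_row)) - ridge * B.T
        H = (w.T @ ZZ).reshape(p, q, q)
        H += eye * (ridge + 1e-8 * (1.0 + np.trace(H, axis1=1, axis2=2))[:, None, None])
        step = np.linalg.solve(H, G.T[:, :, None])[:, :, 0]
        scale = np.ones(p)
        active = np.arange(p)
        ll_pen = ll - 0.5 * ridge * (B**2).sum(axis=1)
        for _ in range(_MAX_HALVINGS):
            B_cand = B[active] + scale[active, None] * step[active]
            mu_c = np.exp(np.clip(off + Z @ B_cand.T, _ETA_LO, _ETA_HI))
            cand = _loglink_ll(Y[:, active], mu_c, phi_row[:, active])
            cand = cand - 0.5 * ridge * (B_cand**2).sum(axis=1)
            good = cand >= ll_pen[active] - 1e-12
            active = active[~good]
            if active.size == 0:
                break
            scale[active] *= 0.5
        if active.size:
            scale[active] = 0.0
        B = B + scale[:, None] * step
        eta = np.clip(off + Z @ B.T, _ETA_LO, _ETA_HI)
        mu = np.exp(eta)
        prev = ll
        ll = _loglink_ll(Y, mu, phi_row)
        rel = np.abs(ll - prev) / (np.abs(prev) + 1.0)
        converged = rel < tol
        if converged.all():
            break
    return BlockFitResult(coef=B, loglik=float(ll.sum()), converged=converged)


def fit_rows_log_link(
    Y: np.ndarray,
    Gamma: np.ndarray,
    phi: np.ndarray,
    U: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> BlockFitResult:
    """Per-observation update of latent scores under the log link, batched.

    eta_i = offset_i + Gamma @ u_i with offset rows log s_i + X_tilde B^T.
    Symmetric counterpart of :func:`fit_nb_glm_log_link`.
    """
    n, p = Y.shape
    r = Gamma.shape[1]
    Y = np.asarray(Y, dtype=float)
    phi_row = phi[None, :]
    C = U.copy()
    ll_warm = _loglink_ll(
        Y, np.exp(np.clip(offset + C @ Gamma.T, _ETA_LO, _ETA_HI)), phi_row, axis=1
    )
    ll_safe = _loglink_ll(Y, np.exp(np.clip(offset, _ETA_LO, _ETA_HI)), phi_row, axis=1)
    bad = ~(ll_warm >= ll_safe)
    C[bad] = 0.0
    mu = np.exp(np.clip(offset + C @ Gamma.T, _ETA_LO, _ETA_HI))
    ll = _loglink_ll(Y, mu, phi_row, axis=1)
    converged = np.zeros(n, dtype=bool)
    eye = np.eye(r)[None, :, :]
    GG = (Gamma[:, :, None] * Gamma[:, None, :]).reshape(p, r * r)
    for _ in range(max_iter):
        w = mu / (1.0 + mu / phi_row)
        G = ((Y - mu) / (1.0 + mu / phi_row)) @ Gamma  # (n, r)
        H = (w @ GG).reshape(n, r, r)
        H += eye * (1e-8 * (1.0 + np.trace(H, axis1=1, axis2=2))[:, None, None])
        step = np.linalg.solve(H, G[:, :, None])[:, :, 0]
        scale = np.ones(n)
        active = np.arange(n)
        for _ in range(_MAX_HALVINGS):
            C_cand = C[active] + scale[active, None] * step[active]
            mu_c = np.exp(np.clip(offset[active] + C_cand @ Gamma.T, _ETA_LO, _ETA_HI))
            cand = _loglink_ll(Y[active], mu_c, phi_row, axis=1)
            good = cand >= ll[active] - 1e-12
            active = active[~good]
            if active.size == 0:
                break
            scale[active] *= 0.5
        if active.size:
            scale[active] = 0.0
        C = C + scale[:, None] * step
        mu = np.exp(np.clip(offset + C @ Gamma.T, _ETA_LO, _ETA_HI))
        prev = ll
        ll = _loglink_ll(Y, mu, phi_row, axis=1)
        rel = np.abs(ll - prev) / (np.abs(prev) + 1.0)
        converged = rel < tol
        if converged.all():
            break
    return BlockFitResult(coef=C, loglik=float(ll.sum()), converged=converged)
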