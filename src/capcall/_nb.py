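"""Negative-binomial one-group fitting shared by the TSS caller and the
differential-expression test.

The model for a single window/region row is

    y_i ~ NB(mu_i, phi),   mu_i = M_i * p,   Var(y_i) = mu_i + phi * mu_i**2

with M_i the per-sample effective library size and p the common relative
abundance of the group. The log-likelihood is strictly concave in
beta = log(p), so a safeguarded Newton iteration converges from the pooled
Poisson start; phi = 0 is the Poisson limit with the exact closed form
p = sum(y) / sum(M).

Counts may be non-integer: prior counts are folded into y before fitting and
the likelihood uses gamma functions throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_LOG2 = np.log(2.0)


def scaled_priors(library_sizes: np.ndarray, prior_count: float) -> np.ndarray:
    """Per-sample prior counts, scaled by library size relative to the mean.

    The scaling makes prior-adjusted abundances exactly invariant under a
    uniform rescaling of all library sizes.
    """
    M = np.asarray(library_sizes, dtype=float)
    if np.any(M <= 0):
        raise ValueError("library sizes must be positive")
    return prior_count * M / M.mean()


def fit_log_abundance(
    y: np.ndarray,
    library_sizes: np.ndarray,
    phi,
    *,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Vectorised MLE of beta = log(p) for rows of `y`.

    Parameters
    ----------
    y : (R, S) or (S,) array of (possibly prior-augmented) counts.
    library_sizes : (S,) or (R, S) positive effective library sizes.
    phi : scalar or (R,) NB dispersion(s), >= 0.

    Returns
    -------
    (R,) array of natural-log abundances. Rows with zero total count return
    -inf (callers apply their documented floor).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    M = np.asarray(library_sizes, dtype=float)
    if M.ndim == 1:
        M = np.broadcast_to(M, y.shape)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[0], float(phi))
    phi = phi[:, None]

    ysum = y.sum(axis=1)
    Msum = M.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(ysum) - np.log(Msum)

    active = (ysum > 0) & (phi[:, 0] > 0)
    if not np.any(active):
        return beta

    b = beta[active]
    ya = y[active]
    Ma = M[active]
    pa = phi[active]
    for _ in range(max_iter):
        mu = Ma * np.exp(b)[:, None]
        denom = 1.0 + pa * mu
        score = ((ya - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        np.clip(step, -5.0, 5.0, out=step)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    beta[active] = b
    return beta


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row sums of the NB log-likelihood (gamma-function form, continuous y)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[0], float(phi))
    phi = phi[:, None]
    out = np.empty(y.shape[0])
    pois = phi[:, 0] <= 0
    if np.any(pois):
        m = mu[pois]
        yy = y[pois]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(yy > 0, yy * np.log(m), 0.0)
        out[pois] = (term - m - gammaln(yy + 1.0)).sum(axis=1)
    if np.any(~pois):
        yy = y[~pois]
        m = mu[~pois]
        r = 1.0 / phi[~pois]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                gammaln(yy + r)
                - gammaln(r)
                - gammaln(yy + 1.0)
                + yy * np.log(m / (m + r))
                - r * np.log1p(m / r)
            )
            ll = np.where((yy == 0) & (m == 0), 0.0, ll)
        out[~pois] = ll.sum(axis=1)
    return out


def beta_to_log2cpm(beta: np.ndarray) -> np.ndarray:
    """log2 counts-per-million from a natural-log relative abundance."""
    return (np.asarray(beta) + np.log(1e6)) / _LOG2
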