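"""Bivariate Gaussian-mixture primitives.

Shared by the synthetic PSP-train generator and the second-order interval
model: joint/marginal/conditional densities of a full-covariance mixture over
adjacent log-interval pairs, iid joint sampling, and two first-order chain
samplers (exact closed-form conditional vs. rejection sampling against a
gridded envelope).  The two chain samplers implement the same Markov kernel
by different routes so one can serve as the oracle for the other.
"""

from __future__ import annotations

import numpy as np

_LOG_2PI = np.log(2.0 * np.pi)


def validate_mixture(weights, means, covariances):
    """Validate and normalize mixture parameter arrays.

    Returns (weights, means, covariances) as float arrays of shape
    (k,), (k, 2), (k, 2, 2). Raises ValueError on a non-simplex weight
    vector or a non-SPD covariance.
    """
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(means, dtype=float)
    cov = np.asarray(covariances, dtype=float)
    if w.ndim != 1 or mu.shape != (w.size, 2) or cov.shape != (w.size, 2, 2):
        raise ValueError(
            f"inconsistent mixture shapes: weights {w.shape}, means {mu.shape}, "
            f"covariances {cov.shape}"
        )
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    for j, c in enumerate(cov):
        if not np.allclose(c, c.T):
            raise ValueError(f"covariance {j} is not symmetric")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValueError(f"covariance {j} is not positive-definite")
    return w, mu, cov


def joint_logpdf(x, weights, means, covariances):
    """Log density of the bivariate mixture at points x of shape (n, 2)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    comps = component_logpdf(x, means, covariances)
    return _logsumexp(comps + np.log(weights), axis=1)


def component_logpdf(x, means, covariances):
    """Per-component bivariate normal log densities, shape (n, k)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    k = means.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        d = x - means[j]
        a, b = covariances[j][0]
        b2, c = covariances[j][1]
        det = a * c - b * b2
        # inverse of a 2x2 SPD matrix, explicit for speed
        q = (c * d[:, 0] ** 2 - 2 * b * d[:, 0] * d[:, 1] + a * d[:, 1] ** 2) / det
        out[:, j] = -0.5 * (q + np.log(det)) - _LOG_2PI
    return out


def _logsumexp(a, axis=None):
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


def marginal_params(weights, means, covariances, axis=0):
    """1-D mixture (weights, means, variances) of the given coordinate."""
    return weights, means[:, axis], covariances[:, axis, axis]


def conditional_params(x, weights, means, covariances):
    """Parameters of p(y | x) for a bivariate Gaussian mixture.

    The conditional is itself a univariate Gaussian mixture: component j keeps
    mean mu_y + (sigma_xy/sigma_xx)(x - mu_x) and variance
    sigma_yy - sigma_xy^2/sigma_xx, with responsibility-reweighted weights
    proportional to w_j N(x; mu_x_j, sigma_xx_j).
    """
    mx = means[:, 0]
    my = means[:, 1]
    sxx = covariances[:, 0, 0]
    sxy = covariances[:, 0, 1]
    syy = covariances[:, 1, 1]
    log_wx = (
        np.log(weights)
        - 0.5 * ((x - mx) ** 2 / sxx + np.log(2.0 * np.pi * sxx))
    )
    log_wx -= _logsumexp(log_wx, axis=0)
    w_c = np.exp(log_wx)
    mu_c = my + sxy / sxx * (x - mx)
    var_c = syy - sxy**2 / sxx
    return w_c, mu_c, var_c


def conditional_pdf(y, x, weights, means, covariances):
    """Density of p(y | x); y may be an array."""
    w_c, mu_c, var_c = conditional_params(x, weights, means, covariances)
    y = np.asarray(y, dtype=float)[..., None]
    dens = np.exp(-0.5 * (y - mu_c) ** 2 / var_c) / np.sqrt(2.0 * np.pi * var_c)
    return (w_c * dens).sum(axis=-1)


def sample_joint(weights, means, covariances, n, rng):
    """n iid pairs from the joint mixture."""
    comp = rng.choice(weights.size, size=n, p=weights)
    out = np.empty((n, 2))
    for j in range(weights.size):
        idx = comp == j
        m = int(idx.sum())
        if m:
            out[idx] = rng.multivariate_normal(means[j], covariances[j], size=m)
    return out


def draw_conditional_exact(x, weights, means, covariances, rng):
    """One exact draw from p(y | x) via component selection."""
    w_c, mu_c, var_c = conditional_params(x, weights, means, covariances)
    j = rng.choice(w_c.size, p=w_c)
    return rng.normal(mu_c[j], np.sqrt(var_c[j]))


def draw_conditional_rejection(
    x,
    weights,
    means,
    covariances,
    rng,
    y_range,
    envelope_factor=1.05,
    grid_points=1024,
    min_acceptance=1e-3,
    batch=64,
    envelope=None,
):
    """One draw from p(y | x) by rejection against a uniform proposal.

    The envelope is ``envelope_factor`` times the maximum of the conditional
    density evaluated on a ``grid_points``-point grid over ``y_range``.  If an
    accepted proposal's density ever exceeds the envelope the envelope is
    rebuilt on a doubled grid and sampling restarts; if the observed acceptance
    probability drops below ``min_acceptance`` a RuntimeError is raised.
    """
    lo, hi = y_range
    if not hi > lo:
        raise ValueError("empty y_range for rejection sampling")
    grid = np.linspace(lo, hi, grid_points)
    if envelope is None:
        envelope = envelope_factor * conditional_pdf(grid, x, weights, means, covariances).max()
    n_proposed = 0
    while True:
        y = rng.uniform(lo, hi, size=batch)
        u = rng.uniform(0.0, envelope, size=batch)
        dens = conditional_pdf(y, x, weights, means, covariances)
        if np.any(dens > envelope):
            # envelope violated: rebuild on a finer grid and restart
            grid = np.linspace(lo, hi, 2 * grid.size)
            envelope = envelope_factor * conditional_pdf(
                grid, x, weights, means, covariances
            ).max()
            n_proposed = 0
            continue
        acc = np.nonzero(u < dens)[0]
        if acc.size:
            return y[acc[0]]
        n_proposed += batch
        if n_proposed > max(1000, 1.0 / min_acceptance):
            raise RuntimeError(
                f"rejection acceptance below {min_acceptance} at x={x:.3g}"
            )


def conditional_envelope(
    x, weights, means, covariances, y_range, envelope_factor=1.05, grid_points=1024
):
    """Rejection envelope: factor times the gridded conditional-density maximum."""
    grid = np.linspace(*y_range, grid_points)
    return envelope_factor * conditional_pdf(grid, x, weights, means, covariances).max()


def sample_chain(
    weights,
    means,
    covariances,
    n,
    rng,
    burn_in=200,
    method="exact",
    y_range=None,
    envelope_factor=1.05,
    grid_points=1024,
    init=None,
):
    """First-order chain of log-intervals: x_{t+1} ~ p(y | x_t).

    Returns ``n`` draws after discarding ``burn_in`` initial draws.  The chain
    starts from the model's x-marginal (or ``init``).  ``method`` selects the
    exact closed-form conditional sampler or the rejection sampler; the two
    implement the same kernel and are kept as independent routes.
    """
    if method not in ("exact", "rejection"):
        raise ValueError(f"unknown chain method {method!r}")
    if method == "rejection" and y_range is None:
        wm, mm, vm = marginal_params(weights, means, covariances, axis=1)
        half = 6.0 * np.sqrt(vm.max())
        y_range = (mm.min() - half, mm.max() + half)
    if init is None:
        wm, mm, vm = marginal_params(weights, means, covariances, axis=0)
        j = rng.choice(wm.size, p=wm)
        x = rng.normal(mm[j], np.sqrt(vm[j]))
    else:
        x = float(init)
    out = np.empty(burn_in + n)
    for t in range(burn_in + n):
        if method == "exact":
            x = draw_conditional_exact(x, weights, means, covariances, rng)
        else:
            x = draw_conditional_rejection(
                x,
                weights,
                means,
                covariances,
                rng,
                y_range,
                envelope_factor=envelope_factor,
                grid_points=grid_points,
            )
        out[t] = x
    return out[burn_in:]


def mean_exp_marginal(weights, means, covariances, axis=1):
    """Closed-form E[exp(Y)] under the chosen marginal (lognormal mixture mean)."""
    w, m, v = marginal_params(weights, means, covariances, axis=axis)
    return float(np.sum(w * np.exp(m + v / 2.0)))
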