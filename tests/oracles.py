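"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's Kalman recursions: moments of the
joint state distribution are built by direct matrix propagation and the
observation log-density is evaluated with scipy's multivariate normal.
"""

import numpy as np
from scipy.stats import multivariate_normal


def joint_gaussian_loglik(spec, y, variances):
    """Exact log-density of the stacked observations under the model."""
    m = spec.state_dim
    n = spec.n_times
    T = spec.transition
    Q = spec.build_Q(variances)
    s2 = float(variances[spec.obs_name])

    # state means and pairwise covariances by direct propagation
    means = [spec.init_mean.copy()]
    for _ in range(1, n):
        means.append(T @ means[-1])
    # cov[t][t] recursively, cross terms via cov(x_s, x_t) = P_s @ (T^{t-s})'
    P = [spec.init_cov.copy()]
    for _ in range(1, n):
        P.append(T @ P[-1] @ T.T + Q)
    powers = [np.eye(m)]
    for _ in range(1, n):
        powers.append(T @ powers[-1])

    rows = []
    obs_vals = []
    obs_time = []
    for t in range(n):
        yt = np.asarray(y[t], float).ravel()
        Zt = spec.design[t]
        for i in range(len(yt)):
            if np.isfinite(yt[i]):
                rows.append((t, Zt[i]))
                obs_vals.append(yt[i])
                obs_time.append(t)
    k = len(obs_vals)
    mu = np.array([z @ means[t] for t, z in rows])
    C = np.empty((k, k))
    for a, (ta, za) in enumerate(rows):
        for b, (tb, zb) in enumerate(rows):
            s, t = min(ta, tb), max(ta, tb)
            cov_states = P[s] @ powers[t - s].T  # cov(x_s, x_t)
            if ta <= tb:
                C[a, b] = za @ cov_states @ zb
            else:
                C[a, b] = za @ cov_states.T @ zb
    C[np.diag_indices(k)] += s2
    return float(
        multivariate_normal(mean=mu, cov=C, allow_singular=True).logpdf(np.array(obs_vals))
    )


def gls_smoothed_means(spec, y, variances):
    """Posterior state means by one dense generalized-least-squares solve."""
    m = spec.state_dim
    n = spec.n_times
    T = spec.transition
    Q = spec.build_Q(variances)
    s2 = float(variances[spec.obs_name])

    means = [spec.init_mean.copy()]
    for _ in range(1, n):
        means.append(T @ means[-1])
    P = [spec.init_cov.copy()]
    for _ in range(1, n):
        P.append(T @ P[-1] @ T.T + Q)
    powers = [np.eye(m)]
    for _ in range(1, n):
        powers.append(T @ powers[-1])

    def state_cov(s, t):
        if s <= t:
            return P[s] @ powers[t - s].T
        return (P[t] @ powers[s - t].T).T

    rows, vals = [], []
    for t in range(n):
        yt = np.asarray(y[t], float).ravel()
        for i in range(len(yt)):
            if np.isfinite(yt[i]):
                rows.append((t, spec.design[t][i]))
                vals.append(yt[i])
    k = len(vals)
    mu_y = np.array([z @ means[t] for t, z in rows])
    S = np.empty((k, k))
    for a, (ta, za) in enumerate(rows):
        for b, (tb, zb) in enumerate(rows):
            S[a, b] = za @ state_cov(ta, tb) @ zb
    S[np.diag_indices(k)] += s2
    resid = np.array(vals) - mu_y
    w = np.linalg.solve(S, resid)
    out = np.empty((n, m))
    for t in range(n):
        cross = np.column_stack([state_cov(t, tb) @ zb for tb, zb in rows])
        out[t] = means[t] + cross @ w
    return out


def random_small_spec(rng, max_T=6):
    """Random well-conditioned little model for property testing."""
    from dielpath.statespace import SSMSpec

    m = int(rng.integers(1, 3))
    n = int(rng.integers(2, max_T + 1))
    A = rng.normal(0, 0.6, (m, m))
    # keep the transition from exploding over 6 steps
    ev = np.max(np.abs(np.linalg.eigvals(A)))
    if ev > 1.0:
        A = A / (ev + 0.1)
    noise_rows = tuple(range(m))
    noise_names = tuple(f"s2_{j}" for j in range(m))
    design = []
    y = []
    for t in range(n):
        c = int(rng.integers(1, 4))
        Z = rng.normal(0, 1, (c, m))
        design.append(Z)
        y.append(rng.normal(0, 1, c))
    spec = SSMSpec(
        transition=A,
        noise_rows=noise_rows,
        noise_names=noise_names,
        design=design,
        init_mean=rng.normal(0, 1, m),
        init_cov=np.eye(m) * float(rng.uniform(0.5, 3.0)),
    )
    variances = {f"s2_{j}": float(rng.uniform(0.05, 1.5)) for j in range(m)}
    variances["sigma2_obs"] = float(rng.uniform(0.05, 1.5))
    return spec, y, variances
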