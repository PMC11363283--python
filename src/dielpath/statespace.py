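"""Linear-Gaussian state-space engine.

Exact Kalman filtering/smoothing, forward-filter backward-sampling (FFBS),
and a Gibbs sampler with conjugate updates.  Both the smooth-trend and the
local-level-with-exogenous-variables models reduce to this one engine:

    state:        x[t] = T x[t-1] + R eta[t],   eta[t] ~ N(0, diag(named vars))
    observation:  y[t,i] = Z[t][i] x[t] + X[t][i] beta + eps,  eps ~ N(0, s2_obs)

Observations are scalar records grouped by time; each time can carry any
number of records (replicates across conditions), each with its own design
row, and NaN records are treated as missing.  Regression terms enter through
per-record covariate rows ``X`` and a coefficient vector ``beta`` updated
conjugately inside the Gibbs sweep.

The Gibbs sweep alternates:  FFBS draw of the state trajectory given
variances and beta; inverse-gamma draws of each named state variance and of
the observation variance; a multivariate-normal draw of beta.  Convergence is
summarized by split-Rhat and effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConvergenceError

_JITTER = 1e-12  # floor on conditional variances


@dataclass
class SSMSpec:
    """Structure of a linear-Gaussian state-space model.

    Parameters
    ----------
    transition : (m, m) array
        State transition matrix T.
    noise_rows : tuple of int
        State index receiving each independent noise term (selector matrix R
        restricted to one unit entry per column, which covers every model in
        this package).
    noise_names : tuple of str
        Variance-parameter name per noise term; repeated names pool their
        sufficient statistics (shared variance).
    design : sequence of (n_t, m) arrays
        Per-time observation design; row i maps the state to scalar record i.
    init_mean, init_cov :
        Prior moments of the state at the first time (diffuse = large
        variance on the diagonal).
    obs_name : str
        Name of the observation variance parameter.
    """

    transition: np.ndarray
    noise_rows: tuple[int, ...]
    noise_names: tuple[str, ...]
    design: Sequence[np.ndarray]
    init_mean: np.ndarray
    init_cov: np.ndarray
    obs_name: str = "sigma2_obs"

    def __post_init__(self) -> None:
        self.transition = np.atleast_2d(np.asarray(self.transition, float))
        m = self.transition.shape[0]
        if self.transition.shape != (m, m):
            raise ValueError("transition must be square")
        if len(self.noise_rows) != len(self.noise_names):
            raise ValueError("noise_rows and noise_names must align")
        if any(not 0 <= r < m for r in self.noise_rows):
            raise ValueError("noise_rows reference invalid state indices")
        self.init_mean = np.asarray(self.init_mean, float).reshape(m)
        self.init_cov = np.atleast_2d(np.asarray(self.init_cov, float))
        self.design = [np.atleast_2d(np.asarray(Z, float)) for Z in self.design]
        for Z in self.design:
            if Z.shape[1] != m:
                raise ValueError("design rows must have state dimension columns")

    @property
    def state_dim(self) -> int:
        return self.transition.shape[0]

    @property
    def n_times(self) -> int:
        return len(self.design)

    def build_Q(self, variances: Mapping[str, float]) -> np.ndarray:
        Q = np.zeros((self.state_dim, self.state_dim))
        for row, name in zip(self.noise_rows, self.noise_names):
            Q[row, row] += max(float(variances[name]), 0.0)
        return Q


def _prepare_obs(spec: SSMSpec, y: Sequence[np.ndarray]):
    """Flatten per-time records, dropping NaN (masked) entries."""
    ys, Zs = [], []
    for t in range(spec.n_times):
        yt = np.asarray(y[t], float).ravel()
        Zt = spec.design[t]
        if len(yt) != Zt.shape[0]:
            raise ValueError(f"time {t}: {len(yt)} records but {Zt.shape[0]} design rows")
        ok = np.isfinite(yt)
        ys.append(yt[ok])
        Zs.append(Zt[ok])
    return ys, Zs


def _filter(spec, ys, Zs, variances, offsets=None):
    """One forward pass.  Returns loglik and per-time predicted/filtered moments."""
    m = spec.state_dim
    T = spec.transition
    Q = spec.build_Q(variances)
    s2 = max(float(variances[spec.obs_name]), _JITTER)
    n = spec.n_times

    a_pred = np.empty((n, m))
    P_pred = np.empty((n, m, m))
    a_filt = np.empty((n, m))
    P_filt = np.empty((n, m, m))
    loglik = 0.0
    a, P = spec.init_mean.copy(), spec.init_cov.copy()
    for t in range(n):
        if t > 0:
            a = T @ a
            P = T @ P @ T.T + Q
            P = 0.5 * (P + P.T)
        a_pred[t], P_pred[t] = a, P
        yt, Zt = ys[t], Zs[t]
        if offsets is not None:
            yt = yt - offsets[t]
        k = len(yt)
        if k:
            v = yt - Zt @ a
            PZ = P @ Zt.T
            F = Zt @ PZ + s2 * np.eye(k)
            L = np.linalg.cholesky(F)
            Fi_v = np.linalg.solve(L.T, np.linalg.solve(L, v))
            loglik += -0.5 * (
                k * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum() + v @ Fi_v
            )
            K = np.linalg.solve(L.T, np.linalg.solve(L, PZ.T)).T
            a = a + K @ v
            P = P - K @ Zt @ P
            P = 0.5 * (P + P.T)
        a_filt[t], P_filt[t] = a, P
    return loglik, a_pred, P_pred, a_filt, P_filt


def kalman_loglik(
    spec: SSMSpec,
    y: Sequence[np.ndarray],
    variances: Mapping[str, float],
    offsets: Sequence[np.ndarray] | None = None,
):
    """Exact marginal log-likelihood plus filtered moments.

    NaN observations are skipped; diffuse initial states are represented by a
    large ``init_cov``.  Raises on non-finite inputs.
    """
    for yt in y:
        if np.any(np.isinf(np.asarray(yt, float))):
            raise ValueError("non-finite (infinite) observation supplied")
    ys, Zs = _prepare_obs(spec, y)
    ll, _, _, a_f, P_f = _filter(spec, ys, Zs, variances, offsets)
    return ll, a_f, P_f


def kalman_smooth(
    spec: SSMSpec,
    y: Sequence[np.ndarray],
    variances: Mapping[str, float],
    offsets: Sequence[np.ndarray] | None = None,
):
    """RTS smoother: marginal smoothed means and covariances per time."""
    ys, Zs = _prepare_obs(spec, y)
    _, a_p, P_p, a_f, P_f = _filter(spec, ys, Zs, variances, offsets)
    n, m = spec.n_times, spec.state_dim
    T = spec.transition
    a_s = a_f.copy()
    P_s = P_f.copy()
    for t in range(n - 2, -1, -1):
        Pp = P_p[t + 1] + _JITTER * np.eye(m)
        C = P_f[t] @ T.T @ np.linalg.inv(Pp)
        a_s[t] = a_f[t] + C @ (a_s[t + 1] - a_p[t + 1])
        P_s[t] = P_f[t] + C @ (P_s[t + 1] - P_p[t + 1]) @ C.T
        P_s[t] = 0.5 * (P_s[t] + P_s[t].T)
    return a_s, P_s


def _sample_mvn(rng, mean, cov):
    """Draw from N(mean, cov), robust to (near-)singular covariance."""
    cov = 0.5 * (cov + cov.T)
    try:
        L = np.linalg.cholesky(cov + _JITTER * np.eye(len(mean)))
        return mean + L @ rng.standard_normal(len(mean))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return mean + (V * np.sqrt(w)) @ rng.standard_normal(len(mean))


def ffbs(
    spec: SSMSpec,
    y: Sequence[np.ndarray],
    variances: Mapping[str, float],
    rng: np.random.Generator,
    offsets: Sequence[np.ndarray] | None = None,
    _prepared=None,
) -> np.ndarray:
    """One exact joint draw of the state trajectory given parameters."""
    if _prepared is None:
        ys, Zs = _prepare_obs(spec, y)
    else:
        ys, Zs = _prepared
    _, a_p, P_p, a_f, P_f = _filter(spec, ys, Zs, variances, offsets)
    n, m = spec.n_times, spec.state_dim
    T = spec.transition
    x = np.empty((n, m))
    x[-1] = _sample_mvn(rng, a_f[-1], P_f[-1])
    for t in range(n - 2, -1, -1):
        Pp = P_p[t + 1] + _JITTER * np.eye(m)
        C = P_f[t] @ T.T @ np.linalg.inv(Pp)
        mean = a_f[t] + C @ (x[t + 1] - a_p[t + 1])
        cov = P_f[t] - C @ P_p[t + 1] @ C.T
        x[t] = _sample_mvn(rng, mean, cov)
    return x


@dataclass
class PosteriorDraws:
    """MCMC output: parameter and state draws with convergence summaries.

    Arrays are indexed ``[chain, draw, ...]``.  ``params`` holds the named
    variances; ``beta`` the regression coefficients (or None); ``states`` the
    state trajectories.  ``rhat`` and ``ess`` cover every scalar parameter.
    """

    params: dict[str, np.ndarray]
    states: np.ndarray
    beta: np.ndarray | None
    rhat: dict[str, float]
    ess: dict[str, float]
    seed: int
    n_chains: int
    n_warmup: int
    n_iter: int

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def stacked_states(self) -> np.ndarray:
        s = self.states
        return s.reshape(-1, s.shape[2], s.shape[3])

    def stacked_beta(self) -> np.ndarray | None:
        return None if self.beta is None else self.beta.reshape(-1, self.beta.shape[2])

    def to_frame(self):
        """Long [chain, draw, parameter, value] table of scalar draws."""
        import pandas as pd

        rows = []
        for name, arr in self.params.items():
            for c in range(arr.shape[0]):
                for d in range(arr.shape[1]):
                    rows.append((c, d, name, arr[c, d]))
        if self.beta is not None:
            for j in range(self.beta.shape[2]):
                for c in range(self.beta.shape[0]):
                    for d in range(self.beta.shape[1]):
                        rows.append((c, d, f"beta[{j}]", self.beta[c, d, j]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def converged(self, threshold: float = 1.1) -> bool:
        return np.isfinite(self.max_rhat) and self.max_rhat <= threshold


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat on a [chain, draw] array."""
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    parts = chains[:, : 2 * half].reshape(c * 2, half)
    W = parts.var(axis=1, ddof=1).mean()
    B = half * parts.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((half - 1) / half + B / (W * half)))


def _ess(chains: np.ndarray) -> float:
    import arviz as az

    return float(np.asarray(az.ess(az.convert_to_dataset(chains))["x"].values).ravel()[0])


def gibbs(
    spec: SSMSpec,
    y: Sequence[np.ndarray],
    *,
    X: Sequence[np.ndarray] | None = None,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_iter: int = 1000,
    seed: int = 1,
    variance_prior: tuple[float, float] = (0.01, 0.01),
    beta_prior_var: float = 100.0,
    fix_variances: Mapping[str, float] | None = None,
    init_variances: Mapping[str, float] | None = None,
    rhat_threshold: float = 1.1,
    check_convergence: bool = False,
) -> PosteriorDraws:
    """Gibbs sampler alternating FFBS with conjugate conditional updates.

    Named state variances and the observation variance receive inverse-gamma
    IG(a0, b0) priors (``variance_prior``); regression coefficients receive
    independent N(0, ``beta_prior_var``) priors.  ``fix_variances`` pins any
    subset of variances (no update), which turns the sampler into a pure FFBS
    state sampler when all are fixed.

    Raises ConvergenceError when ``check_convergence`` is set and any Rhat
    exceeds ``rhat_threshold``.
    """
    ys, Zs = _prepare_obs(spec, y)
    a0, b0 = variance_prior
    names = sorted(set(spec.noise_names)) + [spec.obs_name]
    fixed = dict(fix_variances or {})
    p = 0
    Xs = None
    if X is not None:
        Xs = []
        for t in range(spec.n_times):
            Xt = np.atleast_2d(np.asarray(X[t], float))
            ok = np.isfinite(np.asarray(y[t], float).ravel())
            Xs.append(Xt[ok])
        p = Xs[0].shape[1]
    n_obs_total = sum(len(v) for v in ys)

    # per-variance bookkeeping: which noise terms share each name
    rows_by_name: dict[str, list[int]] = {}
    for row, name in zip(spec.noise_rows, spec.noise_names):
        rows_by_name.setdefault(name, []).append(row)

    keep_params = {n: np.empty((n_chains, n_iter)) for n in names}
    keep_states = np.empty((n_chains, n_iter, spec.n_times, spec.state_dim))
    keep_beta = np.empty((n_chains, n_iter, p)) if p else None

    T = spec.transition
    ss = np.random.SeedSequence(seed)
    for chain, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        variances = {n: 1.0 for n in names}
        if init_variances:
            variances.update(init_variances)
        variances.update(fixed)
        beta = np.zeros(p)
        for it in range(n_warmup + n_iter):
            offsets = [Xt @ beta for Xt in Xs] if p else None
            x = ffbs(spec, y, variances, rng, offsets=offsets, _prepared=(ys, Zs))

            # state variances: increments of the rows each noise term drives
            innov = x[1:] - x[:-1] @ T.T
            for name, rows in rows_by_name.items():
                if name in fixed:
                    continue
                sq = sum(float(np.sum(innov[:, r] ** 2)) for r in rows)
                n_eff = len(rows) * (spec.n_times - 1)
                draw = 1.0 / rng.gamma(a0 + n_eff / 2.0, 1.0 / (b0 + sq / 2.0))
                variances[name] = max(draw, _JITTER)

            # residuals at the observation level
            resid_parts = []
            for t in range(spec.n_times):
                r = ys[t] - Zs[t] @ x[t]
                if p:
                    r = r - Xs[t] @ beta
                resid_parts.append(r)
            if spec.obs_name not in fixed:
                sq = sum(float(r @ r) for r in resid_parts)
                draw = 1.0 / rng.gamma(a0 + n_obs_total / 2.0, 1.0 / (b0 + sq / 2.0))
                variances[spec.obs_name] = max(draw, _JITTER)

            if p:
                s2 = variances[spec.obs_name]
                XtX = np.zeros((p, p))
                Xtr = np.zeros(p)
                for t in range(spec.n_times):
                    r_state = ys[t] - Zs[t] @ x[t]
                    XtX += Xs[t].T @ Xs[t]
                    Xtr += Xs[t].T @ r_state
                prec = XtX / s2 + np.eye(p) / beta_prior_var
                cov = np.linalg.inv(prec)
                mean = cov @ (Xtr / s2)
                beta = _sample_mvn(rng, mean, cov)

            if it >= n_warmup:
                j = it - n_warmup
                for n in names:
                    keep_params[n][chain, j] = variances[n]
                keep_states[chain, j] = x
                if p:
                    keep_beta[chain, j] = beta

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for n in names:
        if n in fixed:
            continue
        logv = np.log(keep_params[n])
        rhat[n] = _split_rhat(logv)
        ess[n] = _ess(logv)
    if p:
        for j in range(p):
            rhat[f"beta[{j}]"] = _split_rhat(keep_beta[:, :, j])
            ess[f"beta[{j}]"] = _ess(keep_beta[:, :, j])
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > rhat_threshold}
    if bad and check_convergence:
        raise ConvergenceError(f"Rhat above {rhat_threshold}: {bad}")

    return PosteriorDraws(
        params=keep_params,
        states=keep_states,
        beta=keep_beta,
        rhat=rhat,
        ess=ess,
        seed=seed,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# convenience constructors


def local_level_spec(n_times: int, n_obs_per_time: int | Sequence[int] = 1,
                     init_var: float = 100.0) -> SSMSpec:
    """Local level model: x[t] = x[t-1] + eta, scalar observations."""
    if np.isscalar(n_obs_per_time):
        counts = [int(n_obs_per_time)] * n_times
    else:
        counts = list(n_obs_per_time)
    design = [np.ones((c, 1)) for c in counts]
    return SSMSpec(
        transition=np.array([[1.0]]),
        noise_rows=(0,),
        noise_names=("sigma2_level",),
        design=design,
        init_mean=np.zeros(1),
        init_cov=np.array([[init_var]]),
    )


def smooth_trend_block() -> tuple[np.ndarray, int]:
    """Transition block of a second-order random-walk trend.

    State is (level_t, level_{t-1}); noise enters the first row.
    """
    return np.array([[2.0, -1.0], [1.0, 0.0]]), 0
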