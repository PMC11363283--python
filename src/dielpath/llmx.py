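"""Local level model with exogenous variables (LLMX).

One diel trend mu[t], indexed by time-of-day and shared across all
condition-series in a fit, follows a first-order random walk

    mu[t] = mu[t-1] + N(0, s2_w).

The fitted level of series s at time t adds linear effects of z-scored
exogenous drivers (ambient temperature, irradiance, and the upstream
transcript's replicate-mean log2 abundance):

    alpha[s,t] = mu[t] + beta_T * z(T[s,t]) + beta_L * z(L[s,t]) + beta_U * z(U[s,t])
    y[s,t,r] ~ Normal(alpha[s,t], s2_obs)

Drivers are z-scored jointly over all series so coefficient magnitudes are
comparable; the standardization constants are stored on the fit and reused
verbatim for counterfactuals and out-of-sample prediction.  A coefficient is
called significant when its 95% credible interval excludes zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataio import SampleGrid, TranscriptSeries, check_shared_grid, log2_matrix
from .exceptions import ExtrapolationError, StandardizationError
from .statespace import SSMSpec, _ess, _split_rhat, gibbs, smooth_trend_block

DEFAULT_EXOG = ("temperature", "irradiance", "upstream")


class LocalLevelExogModel:
    """sklearn-style estimator for the local level model with exogenous drivers.

    Parameters
    ----------
    exog_names : tuple of str
        Names (and order) of exogenous columns expected in ``exog``.
    trend_order : int
        1 = local level (default); 2 = smooth-trend variant.
    upstream_lag : int
        Samples by which the upstream regressor is shifted back (default 0;
        transduction delays are the cross-mapping module's question).
    n_chains, n_warmup, n_iter, seed, rhat_threshold :
        MCMC settings.

    Fitted attributes: ``mu_draws_`` ``[draw x time]``, ``beta_draws_``
    ``[draw x n_exog]``, ``alpha_draws_`` ``[draw x series x time]``,
    ``exog_mean_`` / ``exog_sd_`` standardization constants.
    """

    def __init__(
        self,
        exog_names: tuple[str, ...] = DEFAULT_EXOG,
        trend_order: int = 1,
        upstream_lag: int = 0,
        n_chains: int = 4,
        n_warmup: int = 1000,
        n_iter: int = 1000,
        seed: int = 1,
        rhat_threshold: float = 1.1,
        floor: float | None = None,
        beta_prior_var: float = 100.0,
    ):
        self.exog_names = tuple(exog_names)
        self.trend_order = trend_order
        self.upstream_lag = upstream_lag
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_iter = n_iter
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.floor = floor
        self.beta_prior_var = beta_prior_var

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "exog_names",
                "trend_order",
                "upstream_lag",
                "n_chains",
                "n_warmup",
                "n_iter",
                "seed",
                "rhat_threshold",
                "floor",
                "beta_prior_var",
            )
        }

    def set_params(self, **params) -> "LocalLevelExogModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    @staticmethod
    def _stack_exog(exog, names, S, T) -> np.ndarray:
        """Assemble a [series x time x var] array from dict/DataFrame input."""
        out = np.empty((S, T, len(names)))
        for k, name in enumerate(names):
            v = np.asarray(exog[name], dtype=float)
            if v.shape == (T,):
                v = np.tile(v, (S, 1))
            if v.shape != (S, T):
                raise ValueError(f"exogenous {name!r} must have shape (S,T) or (T,)")
            out[:, :, k] = v
        return out

    def fit(
        self,
        response: list[TranscriptSeries],
        exog,
    ) -> "LocalLevelExogModel":
        """Fit to one or more condition-series and their aligned drivers.

        ``exog`` maps each name in ``exog_names`` to a ``[series x time]``
        array (or a ``[time]`` vector shared by all series).
        """
        grid = check_shared_grid(response)
        T = len(grid)
        S = len(response)
        if S < 2:
            warnings.warn(
                "fewer than 2 series: regression coefficients are weakly identified",
                stacklevel=2,
            )
        raw = self._stack_exog(exog, self.exog_names, S, T)
        if self.upstream_lag and "upstream" in self.exog_names:
            k = self.exog_names.index("upstream")
            lag = self.upstream_lag
            shifted = raw[:, :, k].copy()
            shifted[:, lag:] = raw[:, :-lag, k]
            shifted[:, :lag] = raw[:, [0], k]
            raw[:, :, k] = shifted

        mean = raw.reshape(-1, raw.shape[2]).mean(axis=0)
        sd = raw.reshape(-1, raw.shape[2]).std(axis=0)
        for k, name in enumerate(self.exog_names):
            if sd[k] == 0:
                raise StandardizationError(f"exogenous column {name!r} is constant")
        z = (raw - mean) / sd

        logs = [log2_matrix(s, floor=self.floor) for s in response]
        d = self.trend_order
        p = len(self.exog_names)
        block = smooth_trend_block()[0] if d == 2 else np.array([[1.0]])
        # regression coefficients ride along as constant, noise-free states so
        # FFBS draws them jointly with the trend (their collinearity with a
        # shared diel trend makes separate Gibbs blocks mix poorly)
        m = d + p
        Tm = np.eye(m)
        Tm[:d, :d] = block
        design, y = [], []
        for t in range(T):
            rows, obs = [], []
            for s in range(S):
                row = np.zeros(m)
                row[0] = 1.0
                row[d:] = z[s, t]
                for v in logs[s][t]:
                    rows.append(row)
                    obs.append(v)
            design.append(np.array(rows))
            y.append(np.array(obs))

        init_cov = np.eye(m) * 100.0
        init_cov[d:, d:] = np.eye(p) * self.beta_prior_var
        spec = SSMSpec(
            transition=Tm,
            noise_rows=(0,),
            noise_names=("sigma2_w",),
            design=design,
            init_mean=np.zeros(m),
            init_cov=init_cov,
        )
        draws = gibbs(
            spec,
            y,
            n_chains=self.n_chains,
            n_warmup=self.n_warmup,
            n_iter=self.n_iter,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
        )

        self.series_ = list(response)
        self.grid_ = grid
        self.exog_raw_ = raw
        self.exog_z_ = z
        self.exog_mean_ = mean
        self.exog_sd_ = sd
        self.log2_obs_ = logs
        self.draws_ = draws
        st = draws.stacked_states()
        self.mu_draws_ = st[:, :, 0]
        self.beta_draws_ = st[:, -1, d:]  # constant over t within each draw
        self.sigma2_draws_ = {k: draws.stacked(k) for k in draws.params}
        for k, name in enumerate(self.exog_names):
            bc = draws.states[:, :, -1, d + k]
            draws.rhat[f"beta_{name}"] = _split_rhat(bc)
            draws.ess[f"beta_{name}"] = _ess(bc)
        self.rhat_ = draws.rhat
        # per-draw identity: alpha = mu + sum_k beta_k z_k
        self.alpha_draws_ = (
            self.mu_draws_[:, None, :] + np.einsum("dk,stk->dst", self.beta_draws_, z)
        )
        self.tod_hours_ = grid.hours_from_start() + (
            grid.timepoints[0].hour
            + grid.timepoints[0].minute / 60.0
            + grid.timepoints[0].second / 3600.0
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted; call fit() first")

    # ------------------------------------------------------------------
    def coefficient_summary(self) -> pd.DataFrame:
        """Median, 95% CI and significance flag per exogenous coefficient."""
        self._check_fitted()
        rows = []
        for k, name in enumerate(self.exog_names):
            b = self.beta_draws_[:, k]
            lo, med, hi = np.percentile(b, [2.5, 50, 97.5])
            rows.append(
                {
                    "variable": name,
                    "median": med,
                    "lo": lo,
                    "hi": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        return pd.DataFrame(rows)

    def counterfactual(self, fix: str) -> dict[str, np.ndarray]:
        """Fitted levels with one driver clamped at its grand mean.

        Clamping at the grand mean makes the driver's z-score zero, so its
        regression term drops out of alpha in every posterior draw.
        Returns median and 2.5/97.5% bands, ``[series x time]``.
        """
        self._check_fitted()
        if fix not in self.exog_names:
            raise ValueError(f"unknown variable {fix!r}; choose from {self.exog_names}")
        z = self.exog_z_.copy()
        z[:, :, self.exog_names.index(fix)] = 0.0
        alpha = self.mu_draws_[:, None, :] + np.einsum(
            "dk,stk->dst", self.beta_draws_, z
        )
        lo, med, hi = np.percentile(alpha, [2.5, 50, 97.5], axis=0)
        return {"median": med, "lo": lo, "hi": hi, "draws": alpha}

    def fitted_alpha(self) -> dict[str, np.ndarray]:
        self._check_fitted()
        lo, med, hi = np.percentile(self.alpha_draws_, [2.5, 50, 97.5], axis=0)
        return {"median": med, "lo": lo, "hi": hi}

    def fit_correlation(self) -> float:
        """Pearson r between posterior-median alpha and observed replicate means."""
        self._check_fitted()
        med = np.median(self.alpha_draws_, axis=0)
        obs = np.array([np.nanmean(L, axis=1) for L in self.log2_obs_])
        ok = np.isfinite(obs)
        return float(np.corrcoef(med[ok], obs[ok])[0, 1])

    def predict_series(
        self,
        new_exog,
        new_grid: SampleGrid,
        n_series: int | None = None,
    ) -> dict[str, np.ndarray]:
        """Predict trajectories for new conditions without refitting.

        New drivers are standardized with the *stored* constants; the fitted
        trend is mapped onto the new grid by clock time-of-day with linear
        interpolation between fitted knots (periodic over 24 h when the fit
        spans a full cycle).  Raises ExtrapolationError for times of day the
        fitted trend never visited.
        """
        self._check_fitted()
        T_new = len(new_grid)
        if n_series is None:
            first = np.asarray(new_exog[self.exog_names[0]], dtype=float)
            n_series = 1 if first.ndim == 1 else first.shape[0]
        raw = self._stack_exog(new_exog, self.exog_names, n_series, T_new)
        z = (raw - self.exog_mean_) / self.exog_sd_

        tod_new = new_grid.hours_from_start() + (
            new_grid.timepoints[0].hour
            + new_grid.timepoints[0].minute / 60.0
            + new_grid.timepoints[0].second / 3600.0
        )
        knots = self.tod_hours_
        if len(tod_new) == len(knots) and np.allclose(tod_new, knots):
            # identical sampling schedule: reuse the fitted trend knots directly
            alpha = self.mu_draws_[:, None, :] + np.einsum(
                "dk,stk->dst", self.beta_draws_, z
            )
            lo, med, hi = np.percentile(alpha, [2.5, 50, 97.5], axis=0)
            return {"median": med, "lo": lo, "hi": hi, "draws": alpha}
        span = knots[-1] - knots[0]
        periodic = span >= 24.0 - 1e-9
        x = np.mod(tod_new - knots[0], 24.0) + knots[0] if periodic else tod_new
        if not periodic:
            x = np.where(x > knots[-1], x - 24.0, x)
            if np.any(x < knots[0] - 1e-9) or np.any(x > knots[-1] + 1e-9):
                raise ExtrapolationError(
                    "new time-of-day outside the fitted trend's span"
                )
        mu_interp = np.array(
            [np.interp(x, knots, mu_d) for mu_d in self.mu_draws_]
        )  # [draw, T_new]
        alpha = mu_interp[:, None, :] + np.einsum("dk,stk->dst", self.beta_draws_, z)
        lo, med, hi = np.percentile(alpha, [2.5, 50, 97.5], axis=0)
        return {"median": med, "lo": lo, "hi": hi, "draws": alpha}


# -- functional wrappers ----------------------------------------------------


def fit_llmx(response: list[TranscriptSeries], exog, **config) -> LocalLevelExogModel:
    """Fit the local level model with exogenous variables."""
    return LocalLevelExogModel(**config).fit(response, exog)


def coefficient_summary(fit: LocalLevelExogModel) -> pd.DataFrame:
    return fit.coefficient_summary()


def counterfactual(fit: LocalLevelExogModel, fix: str) -> dict[str, np.ndarray]:
    return fit.counterfactual(fix)


def predict_series(fit: LocalLevelExogModel, new_exog, new_grid: SampleGrid, **kw):
    return fit.predict_series(new_exog, new_grid, **kw)


def upstream_regressor(series: TranscriptSeries, floor: float | None = None) -> np.ndarray:
    """Replicate-mean log2 abundance of an upstream transcript."""
    return series.log2_replicate_mean(floor=floor)
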