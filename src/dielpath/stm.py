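"""Smooth trend model (STM) for comparing conditions over a diel cycle.

The baseline condition follows a latent trend mu1; each further condition c
adds a difference component delta_c, so its trend is mu_c = mu1 + delta_c.
Each component follows a second-order random walk (a "smooth trend"),

    mu[t] = 2*mu[t-1] - mu[t-2] + N(0, s2_mu),

which penalizes curvature rather than level changes and yields the smooth
credible bands typical of this model class.  Observations are replicate log2
abundances with shared Gaussian noise.  A timepoint is called significantly
different between conditions when the pointwise 95% credible interval of the
relevant delta excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TranscriptSeries, check_shared_grid, log2_matrix
from .exceptions import ConvergenceError, IdentifiabilityError
from .statespace import PosteriorDraws, SSMSpec, gibbs, smooth_trend_block


def _component_block(order: int) -> np.ndarray:
    if order == 2:
        return smooth_trend_block()[0]
    if order == 1:
        return np.array([[1.0]])
    raise ValueError("trend_order must be 1 or 2")


class SmoothTrendModel:
    """sklearn-style estimator for the smooth trend model.

    Parameters
    ----------
    trend_order : int
        2 for a smooth trend (default), 1 for a local level.
    n_chains, n_warmup, n_iter, seed :
        MCMC settings.
    rhat_threshold : float
        Convergence flag threshold on split-Rhat.
    floor : float or None
        Positivity floor passed to the log2 transform (None = half the
        smallest positive observation, per series).

    Fitted attributes (trailing underscore) hold stacked posterior draws:
    ``mu_draws_[c]`` is the ``[draw x time]`` trend of condition c,
    ``delta_draws_[c-1]`` the difference of condition c from baseline.
    """

    def __init__(
        self,
        trend_order: int = 2,
        n_chains: int = 4,
        n_warmup: int = 1000,
        n_iter: int = 1000,
        seed: int = 1,
        rhat_threshold: float = 1.1,
        floor: float | None = None,
    ):
        self.trend_order = trend_order
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_iter = n_iter
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.floor = floor

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "trend_order",
                "n_chains",
                "n_warmup",
                "n_iter",
                "seed",
                "rhat_threshold",
                "floor",
            )
        }

    def set_params(self, **params) -> "SmoothTrendModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, series_by_condition: list[TranscriptSeries]) -> "SmoothTrendModel":
        """Fit to 1-3 conditions sharing one sampling grid (2-3 typical)."""
        if not 1 <= len(series_by_condition) <= 3:
            raise ValueError("supply 1 to 3 condition series")
        grid = check_shared_grid(series_by_condition)
        T = len(grid)
        if T < 4:
            raise IdentifiabilityError("need at least 4 timepoints")
        n_cond = len(series_by_condition)
        d = self.trend_order
        block = _component_block(d)

        m = d * n_cond
        Tm = np.zeros((m, m))
        noise_rows, noise_names = [], []
        for c in range(n_cond):
            Tm[c * d : (c + 1) * d, c * d : (c + 1) * d] = block
            noise_rows.append(c * d)
            noise_names.append("sigma2_mu1" if c == 0 else f"sigma2_delta{c}")

        logs = [log2_matrix(s, floor=self.floor) for s in series_by_condition]
        design, y = [], []
        for t in range(T):
            rows, obs = [], []
            for c, L in enumerate(logs):
                row = np.zeros(m)
                row[0] = 1.0
                if c > 0:
                    row[c * d] = 1.0
                for v in L[t]:
                    rows.append(row)
                    obs.append(v)
            design.append(np.array(rows))
            y.append(np.array(obs))

        spec = SSMSpec(
            transition=Tm,
            noise_rows=tuple(noise_rows),
            noise_names=tuple(noise_names),
            design=design,
            init_mean=np.zeros(m),
            init_cov=np.eye(m) * 100.0,
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

        st = draws.stacked_states()  # [draw, T, m]
        self.series_ = list(series_by_condition)
        self.grid_ = grid
        self.log2_obs_ = logs
        self.draws_ = draws
        self.mu_draws_ = [st[:, :, 0]]
        self.delta_draws_ = []
        for c in range(1, n_cond):
            dd = st[:, :, c * d]
            self.delta_draws_.append(dd)
            self.mu_draws_.append(st[:, :, 0] + dd)  # per-draw identity mu_c = mu1 + delta_c
        self.sigma2_draws_ = {k: draws.stacked(k) for k in draws.params}
        self.rhat_ = draws.rhat
        self.summary_ = self._summarize()
        return self

    def _summarize(self) -> pd.DataFrame:
        rows = []
        comps = [("mu1", self.mu_draws_[0])]
        for c in range(1, len(self.mu_draws_)):
            comps.append((f"mu{c + 1}", self.mu_draws_[c]))
            comps.append((f"delta{c}" if c > 1 else "delta", self.delta_draws_[c - 1]))
        for name, arr in comps:
            lo, med, hi = np.percentile(arr, [2.5, 50, 97.5], axis=0)
            for t in range(arr.shape[1]):
                rows.append(
                    {"component": name, "t": t, "median": med[t], "lo": lo[t], "hi": hi[t]}
                )
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted; call fit() first")

    # -- post-fit analyses --------------------------------------------------
    def difference_significance(self, force: bool = False) -> list[dict]:
        """Maximal contiguous windows where a delta's 95% CI excludes zero.

        Returns dicts with component name, first/last timepoint index and the
        sign of the difference.  Refuses to interpret an unconverged fit
        unless ``force`` is set.
        """
        self._check_fitted()
        if not force and not self.draws_.converged(self.rhat_threshold):
            raise ConvergenceError(
                f"max Rhat {self.draws_.max_rhat:.3f} above {self.rhat_threshold}; "
                "pass force=True to override"
            )
        windows = []
        for c, dd in enumerate(self.delta_draws_, start=1):
            name = "delta" if c == 1 else f"delta{c}"
            lo, hi = np.percentile(dd, [2.5, 97.5], axis=0)
            sig = (lo > 0) | (hi < 0)
            sign = np.where(lo > 0, 1, -1)
            t = 0
            while t < len(sig):
                if sig[t]:
                    start = t
                    while t + 1 < len(sig) and sig[t + 1] and sign[t + 1] == sign[start]:
                        t += 1
                    windows.append(
                        {
                            "component": name,
                            "start": int(start),
                            "end": int(t),
                            "sign": int(sign[start]),
                        }
                    )
                t += 1
        return windows

    def significance_mask(self) -> np.ndarray:
        """Boolean [component x time] mask of 95%-CI exclusion of zero."""
        self._check_fitted()
        masks = []
        for dd in self.delta_draws_:
            lo, hi = np.percentile(dd, [2.5, 97.5], axis=0)
            masks.append((lo > 0) | (hi < 0))
        return np.array(masks)

    def fitted_medians(self) -> np.ndarray:
        """Posterior-median trend per condition, [condition x time]."""
        self._check_fitted()
        return np.array([np.median(mu, axis=0) for mu in self.mu_draws_])

    def observed_means(self) -> np.ndarray:
        """Replicate-mean observed log2 abundance, [condition x time]."""
        self._check_fitted()
        return np.array(
            [np.nanmean(L, axis=1) for L in self.log2_obs_]
        )

    def residuals(self) -> pd.DataFrame:
        """Replicate-mean observed minus posterior-median trend per condition."""
        fit = self.fitted_medians()
        obs = self.observed_means()
        rows = []
        for c in range(fit.shape[0]):
            for t in range(fit.shape[1]):
                rows.append(
                    {
                        "condition": self.series_[c].condition,
                        "t": t,
                        "fitted": fit[c, t],
                        "residual": obs[c, t] - fit[c, t],
                    }
                )
        return pd.DataFrame(rows)

    def residual_diagnostics(self) -> dict[str, pd.DataFrame]:
        """Fitted-vs-residual pairs and normal Q-Q coordinates of residuals."""
        res = self.residuals()
        r = np.sort(res["residual"].to_numpy())
        n = len(r)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        qq = pd.DataFrame({"theoretical": theo, "observed": r})
        return {"fitted_vs_residual": res, "qq": qq}

    def fit_correlation(self) -> float:
        """Pearson r between posterior-median fit and observed replicate means."""
        fit = self.fitted_medians().ravel()
        obs = self.observed_means().ravel()
        if np.nanstd(obs) == 0:
            raise ValueError("observed means have zero variance; correlation undefined")
        ok = np.isfinite(obs)
        return float(np.corrcoef(fit[ok], obs[ok])[0, 1])


@dataclass
class STMFit:
    """Lightweight result view around a fitted SmoothTrendModel."""

    model: SmoothTrendModel

    @property
    def summary(self) -> pd.DataFrame:
        return self.model.summary_

    @property
    def draws(self) -> PosteriorDraws:
        return self.model.draws_


# -- functional wrappers ----------------------------------------------------


def fit_stm(series_by_condition: list[TranscriptSeries], **config) -> SmoothTrendModel:
    """Fit the smooth trend model; thin wrapper over SmoothTrendModel."""
    return SmoothTrendModel(**config).fit(series_by_condition)


def difference_significance(fit: SmoothTrendModel, force: bool = False) -> list[dict]:
    return fit.difference_significance(force=force)


def residual_diagnostics(fit: SmoothTrendModel) -> dict[str, pd.DataFrame]:
    return fit.residual_diagnostics()


def fit_correlation(fit: SmoothTrendModel) -> float:
    return fit.fit_correlation()
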