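"""Convergent cross-mapping (CCM) with diel-surrogate significance.

CCM asks whether the attractor reconstructed from a putative *effect* series
Y retains an imprint of a putative *cause* X: delay-coordinate vectors of Y
are used to predict X by simplex projection, and prediction skill (Pearson
rho between predicted and observed X) that exceeds a surrogate null band and
grows with the number of reconstruction points ("library size") is evidence
that X drives Y.  Note the inversion: causality X -> Y is tested by
predicting X *from* Y's manifold.

A time-to-prediction offset tp probes transduction delays: at tp < 0 the
manifold predicts X's past, i.e. X leads Y.

Significance is assessed against diel surrogates of the cause: series that
keep X's mean time-of-day profile but randomize the ordering of its residual
fluctuations, destroying any cause-specific coupling while retaining the
shared 24-h oscillation that would otherwise inflate skill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import TranscriptSeries
from .exceptions import CycleError, LengthError, LibraryError


# ---------------------------------------------------------------------------
# embedding


@dataclass
class Manifold:
    """Delay-coordinate embedding of one series.

    ``vectors[i]`` = (x[t], x[t-tau], ..., x[t-(E-1)tau]) at t = ``times[i]``;
    vectors never span the boundaries of concatenated segments.
    """

    source_id: str
    E: int
    tau: int
    vectors: np.ndarray
    times: np.ndarray
    segments: np.ndarray


def _as_segments(n: int, segments) -> np.ndarray:
    if segments is None:
        return np.zeros(n, dtype=int)
    seg = np.asarray(segments, dtype=int)
    if seg.shape != (n,):
        raise ValueError("segments must label every sample")
    return seg


def embed(x: np.ndarray, E: int, tau: int = 1, segments=None, source_id: str = "") -> Manifold:
    """Build the shadow manifold of ``x`` (within-segment vectors only)."""
    x = np.asarray(x, dtype=float)
    seg = _as_segments(len(x), segments)
    vecs, times = [], []
    for t in range(len(x)):
        lags = t - tau * np.arange(E)
        if lags[-1] < 0 or seg[lags[-1]] != seg[t]:
            continue
        if not np.all(seg[lags] == seg[t]):
            continue
        vecs.append(x[lags])
        times.append(t)
    if not vecs:
        raise LengthError(f"series too short for E={E}, tau={tau}")
    return Manifold(source_id, E, tau, np.array(vecs), np.array(times), seg)


def _neighbor_predict(
    dist_row: np.ndarray,
    lib_times: np.ndarray,
    lib_targets: np.ndarray,
    E: int,
    t_query: int,
    theiler: int,
) -> float:
    """Simplex prediction from E+1 nearest library points (ties by time)."""
    ok = np.abs(lib_times - t_query) > theiler
    if ok.sum() < E + 1:
        return np.nan
    d = dist_row[ok]
    tt = lib_times[ok]
    tv = lib_targets[ok]
    order = np.lexsort((tt, d))[: E + 1]
    dn = d[order]
    d1 = max(dn[0], 1e-12)
    w = np.exp(-dn / d1)
    return float(np.sum(w * tv[order]) / np.sum(w))


def _pairwise_dist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.sqrt(
        np.maximum(
            (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * A @ B.T, 0.0
        )
    )


def _skill(obs: np.ndarray, pred: np.ndarray) -> float:
    ok = np.isfinite(obs) & np.isfinite(pred)
    if ok.sum() < 3 or np.std(obs[ok]) == 0 or np.std(pred[ok]) == 0:
        return np.nan
    return float(np.corrcoef(obs[ok], pred[ok])[0, 1])


def select_embedding(
    x: np.ndarray,
    E_range=range(1, 11),
    tp: int = 1,
    tau: int = 1,
    segments=None,
    low_skill_warning: float = 0.2,
):
    """Choose the embedding dimension by leave-one-out simplex forecast skill.

    For each E the series forecasts itself ``tp`` steps ahead from its own
    manifold (the query point and its Theiler neighborhood excluded); the
    optimal E maximizes Pearson skill, with ties going to the smallest E.
    Returns ``(table, E_opt)`` where table rows are (E, skill).
    """
    x = np.asarray(x, dtype=float)
    E_range = list(E_range)
    if len(x) < max(E_range) * 2:
        raise LengthError(
            f"series length {len(x)} < 2*max(E_range) = {2 * max(E_range)}"
        )
    seg = _as_segments(len(x), segments)
    rows = []
    for E in E_range:
        man = embed(x, E, tau, seg)
        valid = [
            (i, t)
            for i, t in enumerate(man.times)
            if t + tp < len(x) and t + tp >= 0 and seg[t + tp] == seg[t]
        ]
        if len(valid) < E + 2:
            rows.append((E, np.nan))
            continue
        idx = np.array([i for i, _ in valid])
        D = _pairwise_dist(man.vectors[idx], man.vectors[idx])
        times = man.times[idx]
        targets = x[times + tp]
        preds = np.array(
            [
                _neighbor_predict(D[q], times, targets, E, times[q], E)
                for q in range(len(idx))
            ]
        )
        rows.append((E, _skill(targets, preds)))
    skills = np.array([s for _, s in rows], dtype=float)
    if np.all(np.isnan(skills)):
        raise LengthError("no embedding dimension admits a forecast")
    best = int(np.nanargmax(skills))  # first max -> smallest E on ties
    E_opt = E_range[best]
    if np.nanmax(skills) < low_skill_warning:
        warnings.warn(
            f"best simplex skill {np.nanmax(skills):.3f} is low; "
            "embedding choice is weakly informed",
            stacklevel=2,
        )
    return rows, E_opt


# ---------------------------------------------------------------------------
# cross mapping


def _cross_map_setup(effect, cause, E, tau, tp, segments):
    effect = np.asarray(effect, dtype=float)
    cause = np.asarray(cause, dtype=float)
    if effect.shape != cause.shape:
        raise ValueError("effect and cause must share a grid")
    seg = _as_segments(len(effect), segments)
    man = embed(effect, E, tau, seg)
    valid = np.array(
        [
            i
            for i, t in enumerate(man.times)
            if 0 <= t + tp < len(cause) and seg[t + tp] == seg[t]
        ]
    )
    if len(valid) == 0:
        raise LengthError(f"no valid points at tp={tp}")
    vectors = man.vectors[valid]
    times = man.times[valid]
    targets_idx = times + tp
    return vectors, times, targets_idx, cause


def cross_map(
    effect: np.ndarray,
    cause: np.ndarray,
    E: int,
    tau: int = 1,
    tp: int = 0,
    libraries=None,
    n_draws: int = 100,
    seed: int = 0,
    segments=None,
) -> np.ndarray:
    """Cross-map skill rho for each library size.

    The manifold of the effect is used to predict ``cause[t + tp]`` from the
    E+1 nearest neighbors of each query vector, with exponential weights
    ``exp(-d_i/d_1)`` and a Theiler window excluding |dt| <= E.  For each
    library size L, ``n_draws`` random subsets of L manifold points are used
    and the mean Pearson skill is returned (the full library is evaluated
    deterministically once).
    """
    vectors, times, targets_idx, cause = _cross_map_setup(
        effect, cause, E, tau, tp, segments
    )
    n_pool = len(vectors)
    if libraries is None:
        libraries = [n_pool]
    rng = np.random.default_rng(seed)
    D = _pairwise_dist(vectors, vectors)
    targets = np.asarray(cause, dtype=float)[targets_idx]

    rhos = np.empty(len(libraries))
    for li, L in enumerate(libraries):
        L = int(L)
        if L < E + 2:
            raise LibraryError(f"library size {L} < E+2 = {E + 2}")
        if L > n_pool:
            raise LibraryError(f"library size {L} exceeds pool {n_pool}")
        if L == n_pool:
            sub_draws = [np.arange(n_pool)]
        else:
            sub_draws = [rng.choice(n_pool, L, replace=False) for _ in range(n_draws)]
        vals = [
            _skill(targets, _predict_from_library(D, times, targets, E, sub))
            for sub in sub_draws
        ]
        rhos[li] = np.nanmean(vals)
    return rhos


def _predict_from_library(D, times, targets, E, sub):
    """Vectorized simplex prediction of every query from one library subset.

    Ties in distance are broken by library time index; queries whose Theiler
    exclusion leaves fewer than E+1 library points yield NaN.
    """
    n_pool = D.shape[0]
    k = E + 1
    Dsub = D[:, sub].copy()
    t_lib = times[sub]
    excl = np.abs(t_lib[None, :] - times[:, None]) <= E
    Dsub[excl] = np.inf
    # stable tie-break: add an infinitesimal ramp in library-time order
    order_rank = np.argsort(np.argsort(t_lib))
    key = Dsub + order_rank[None, :] * 1e-12
    nn = np.argpartition(key, kth=min(k - 1, key.shape[1] - 1), axis=1)[:, :k]
    rows = np.arange(n_pool)[:, None]
    dn = Dsub[rows, nn]
    inner = np.argsort(key[rows, nn], axis=1)
    nn = nn[rows, inner]
    dn = Dsub[rows, nn]
    bad = ~np.isfinite(dn).all(axis=1)
    d1 = np.maximum(dn[:, :1], 1e-12)
    with np.errstate(invalid="ignore", over="ignore"):
        w = np.exp(-dn / d1)
    w = np.where(np.isfinite(dn), w, 0.0)
    wsum = w.sum(axis=1)
    pred = (w * targets[sub][nn]).sum(axis=1) / np.where(wsum > 0, wsum, np.nan)
    pred[bad] = np.nan
    return pred


def _full_library_weights(vectors, times, E):
    """Sparse simplex weights of every query against the full library.

    Returns (W, ok) with W ``[n, n]`` rows summing to 1 over the E+1 selected
    neighbors, so predictions for any target vector are ``W @ target_values``.
    """
    n = len(vectors)
    D = _pairwise_dist(vectors, vectors)
    W = np.zeros((n, n))
    ok = np.ones(n, dtype=bool)
    for q in range(n):
        mask = np.abs(times - times[q]) > E
        if mask.sum() < E + 1:
            ok[q] = False
            continue
        idx = np.flatnonzero(mask)
        order = idx[np.lexsort((times[idx], D[q, idx]))[: E + 1]]
        dn = D[q, order]
        d1 = max(dn[0], 1e-12)
        w = np.exp(-dn / d1)
        W[q, order] = w / w.sum()
    return W, ok


def make_diel_surrogates(
    x: np.ndarray,
    samples_per_day: int,
    n: int = 1000,
    seed: int = 0,
    segments=None,
) -> np.ndarray:
    """Diel surrogates: preserve the time-of-day mean profile, shuffle residuals.

    The per-slot mean m[j] (j = sample index modulo ``samples_per_day``,
    restarting in each segment) is computed once; residuals e[t] = x[t] -
    m[slot(t)] are permuted uniformly over the whole series and added back.
    The surrogate ensemble therefore shares the original's diel oscillation
    and its residual value multiset exactly.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * samples_per_day:
        raise CycleError(
            f"need >= 2 diel cycles ({2 * samples_per_day} samples); got {len(x)}"
        )
    seg = _as_segments(len(x), segments)
    slot = np.empty(len(x), dtype=int)
    for s in np.unique(seg):
        w = np.flatnonzero(seg == s)
        slot[w] = np.arange(len(w)) % samples_per_day
    m = np.array([x[slot == j].mean() for j in range(samples_per_day)])
    resid = x - m[slot]
    rng = np.random.default_rng(seed)
    out = np.empty((n, len(x)))
    for i in range(n):
        out[i] = m[slot] + resid[rng.permutation(len(x))]
    return out


@dataclass
class CCMResult:
    """Cross-map scan over time-to-prediction and library size."""

    cause: str
    effect: str
    E: int
    tau: int
    tp_grid: tuple[int, ...]
    libraries: dict[int, np.ndarray]         # tp -> library sizes
    rho: dict[int, np.ndarray]               # tp -> rho(L) (NaN where not run)
    rho_full: dict[int, float]               # tp -> rho at max library
    surrogate_lo: dict[int, float]           # tp -> 2.5% band at max library
    surrogate_hi: dict[int, float]           # tp -> 97.5% band
    significant: dict[int, bool]
    convergent: dict[int, bool]
    n_surrogates: int
    seed: int

    @property
    def significant_tps(self) -> list[int]:
        return [tp for tp in self.tp_grid if self.significant[tp]]


def _series_values(obj, floor=None):
    if isinstance(obj, TranscriptSeries):
        return obj.log2_replicate_mean(floor=floor), obj.gene_id
    return np.asarray(obj, dtype=float), getattr(obj, "name", "series")


def ccm_test(
    effect,
    cause,
    tp_grid=range(-8, 3),
    *,
    E_range=range(1, 11),
    tau: int = 1,
    n_surrogates: int = 1000,
    samples_per_day: int = 12,
    seed: int = 0,
    segments=None,
    libraries=None,
    n_draws: int = 100,
) -> CCMResult:
    """Full CCM analysis of whether ``cause`` drives ``effect``.

    ``effect`` and ``cause`` may be TranscriptSeries (replicate-mean log2 is
    used), lists of TranscriptSeries (conditions concatenated with segment
    boundaries recorded), or plain arrays.  The embedding dimension is chosen
    on the effect series; each tp in ``tp_grid`` is scanned; significance at
    a tp means the full-library skill exceeds the 97.5th percentile of skills
    obtained with diel surrogates of the cause; the convergence flag
    additionally requires skill to increase from the smallest to the largest
    library size.
    """
    if isinstance(effect, (list, tuple)):
        parts_e = [_series_values(s)[0] for s in effect]
        parts_c = [_series_values(s)[0] for s in cause]
        seg = np.concatenate([np.full(len(p), i) for i, p in enumerate(parts_e)])
        y = np.concatenate(parts_e)
        x = np.concatenate(parts_c)
        name_e = getattr(effect[0], "gene_id", "effect")
        name_c = getattr(cause[0], "gene_id", "cause")
    else:
        y, name_e = _series_values(effect)
        x, name_c = _series_values(cause)
        seg = _as_segments(len(y), segments)

    _, E = select_embedding(y, E_range=E_range, tau=tau, segments=seg)
    rng = np.random.default_rng(seed)
    surr = make_diel_surrogates(
        x, samples_per_day, n=n_surrogates, seed=int(rng.integers(2**31 - 1)), segments=seg
    )

    tp_grid = tuple(int(t) for t in tp_grid)
    out_lib, out_rho, out_full = {}, {}, {}
    out_lo, out_hi, out_sig, out_conv = {}, {}, {}, {}
    for tp in tp_grid:
        vectors, times, targets_idx, _ = _cross_map_setup(y, x, E, tau, tp, seg)
        n_pool = len(vectors)
        W, okq = _full_library_weights(vectors, times, E)
        obs = x[targets_idx]
        pred = W @ obs
        rho_full = _skill(obs[okq], pred[okq])

        # surrogate band at full library: same weights, surrogate targets
        s_obs = surr[:, targets_idx]
        s_pred = s_obs @ W.T
        s_rho = np.array(
            [_skill(s_obs[i, okq], s_pred[i, okq]) for i in range(n_surrogates)]
        )
        lo, hi = np.nanpercentile(s_rho, [2.5, 97.5])
        sig = bool(np.isfinite(rho_full) and rho_full > hi)

        if libraries is None:
            lo_L = E + 2
            libs = np.unique(np.linspace(lo_L, n_pool, 8).astype(int))
        else:
            libs = np.unique([L for L in libraries if E + 2 <= L <= n_pool])
        rho_L = np.full(len(libs), np.nan)
        conv = False
        if sig:
            rho_L = cross_map(
                y, x, E, tau=tau, tp=tp, libraries=libs, n_draws=n_draws,
                seed=int(rng.integers(2**31 - 1)), segments=seg,
            )
            conv = bool(rho_L[-1] - rho_L[0] > 0)
        out_lib[tp] = libs
        out_rho[tp] = rho_L
        out_full[tp] = rho_full
        out_lo[tp], out_hi[tp] = float(lo), float(hi)
        out_sig[tp] = sig
        out_conv[tp] = conv and sig

    return CCMResult(
        cause=name_c,
        effect=name_e,
        E=E,
        tau=tau,
        tp_grid=tp_grid,
        libraries=out_lib,
        rho=out_rho,
        rho_full=out_full,
        surrogate_lo=out_lo,
        surrogate_hi=out_hi,
        significant=out_sig,
        convergent=out_conv,
        n_surrogates=n_surrogates,
        seed=seed,
    )


class ConvergentCrossMapping:
    """sklearn-style wrapper: ``fit(effect, cause)`` runs the full CCM scan."""

    def __init__(
        self,
        tp_grid=tuple(range(-8, 3)),
        E_range=tuple(range(1, 11)),
        tau: int = 1,
        n_surrogates: int = 1000,
        samples_per_day: int = 12,
        n_draws: int = 100,
        seed: int = 0,
    ):
        self.tp_grid = tuple(tp_grid)
        self.E_range = tuple(E_range)
        self.tau = tau
        self.n_surrogates = n_surrogates
        self.samples_per_day = samples_per_day
        self.n_draws = n_draws
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "tp_grid",
                "E_range",
                "tau",
                "n_surrogates",
                "samples_per_day",
                "n_draws",
                "seed",
            )
        }

    def set_params(self, **params) -> "ConvergentCrossMapping":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, effect, cause, segments=None) -> "ConvergentCrossMapping":
        self.result_ = ccm_test(
            effect,
            cause,
            tp_grid=self.tp_grid,
            E_range=self.E_range,
            tau=self.tau,
            n_surrogates=self.n_surrogates,
            samples_per_day=self.samples_per_day,
            n_draws=self.n_draws,
            seed=self.seed,
            segments=segments,
        )
        return self
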