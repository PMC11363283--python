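"""Synthetic study-condition generators.

These generators emulate the structure of a field campaign on a clock ->
sigma-factor -> chloroplast-promoter signaling cascade: environmental logs at
5-min resolution, 2-h transcript sampling over 24-48 h with six replicate
plants, log-normal observation noise, a clock transcript peaking at dawn that
drives a downstream transcript which also responds to temperature, which in
turn drives a light-gated chloroplast transcript.  A coupled logistic map is
provided as a benchmark system for cross-mapping, and shuffle/white nulls as
negative controls.

All randomness is seeded explicitly; the same seed reproduces the same
series bit for bit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .dataio import EnvSeries, SampleGrid, TranscriptSeries, aggregate_env, make_diel_grid
from .exceptions import StabilityError

#: environment profiles: baseline and diel amplitude (degC), afternoon peak
#: hour, AR(1) stationary sd (degC) and per-step phi of the synoptic anomaly
#: at 5-min resolution, peak irradiance (W m^-2) and log-scale cloud-noise sd.
#: The anomaly correlation time (~2 h) mimics weather fronts; clouds are
#: likewise temporally correlated rather than white.
ENV_PROFILES = {
    "cool": dict(base=7.0, amp=5.5, peak_hour=14.0, phi=0.996, sd=1.0,
                 irr_peak=800.0, cloud_sd=0.4),
    "warm": dict(base=23.0, amp=3.0, peak_hour=14.0, phi=0.996, sd=0.8,
                 irr_peak=400.0, cloud_sd=0.4),
}


@dataclass
class CascadeParams:
    """Parameters of the synthetic clock -> mid -> downstream cascade.

    Coefficients are on the log2 scale against z-scored drivers; lags are in
    sampling steps and represent signal-transduction delays between pathway
    components.
    """

    clock_amplitude: float = 2.0          # log2 units
    clock_peak_phase: float = 0.0         # hours after dawn
    beta_temp_C: float = 0.4              # clock's own temperature sensitivity
    clock_noise_sd: float = 0.8           # intrinsic clock wander, log2 units
    clock_noise_phi: float = 0.9          # its AR(1) coefficient per sample
    beta_temp_S: float = -0.5
    beta_irr_S: float = 0.2
    beta_up_S: float = 0.8
    beta_temp_P: float = 0.5
    beta_up_P: float = 0.8
    lag1: int = 1                         # clock -> mid delay, samples
    lag2: int = 1                         # mid -> downstream delay, samples
    light_gate: bool = True
    obs_sd: float = 0.25                  # log2 units
    n_replicates: int = 6
    base_S: float = 0.0                   # constant latent trends, log2 units
    base_P: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.obs_sd < 0:
            raise ValueError("obs_sd must be >= 0")
        if self.lag1 < 0 or self.lag2 < 0:
            raise ValueError("lags must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_environment(
    profile: str,
    n_days: int = 2,
    step_minutes: int = 5,
    seed: int = 0,
    start: dt.datetime | None = None,
    dawn_hour: float = 6.0,
    dusk_hour: float = 18.0,
) -> EnvSeries:
    """Diel temperature and irradiance records.

    Temperature is a baseline plus a diel sinusoid (afternoon peak) plus
    stationary AR(1) noise; irradiance is a half-sine across the photoperiod
    modulated by multiplicative log-normal "cloud" noise and exactly zero at
    night.  The ``cool`` profile spans roughly 0-14 degC, the ``warm``
    profile stays above 17 degC.
    """
    if profile not in ENV_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(ENV_PROFILES)}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    p = ENV_PROFILES[profile]
    rng = np.random.default_rng(seed)
    if start is None:
        start = dt.datetime(2015, 3, 20, 0, 0)
    n = int(n_days * 24 * 60 / step_minutes) + 1
    times = tuple(start + dt.timedelta(minutes=step_minutes * i) for i in range(n))
    hour = np.array([(t - start).total_seconds() / 3600.0 for t in times])
    tod = np.array([t.hour + t.minute / 60.0 for t in times])

    # phi is calibrated for 5-min records; rescale for other steps so the
    # anomaly's correlation time is preserved
    phi = float(p["phi"]) ** (step_minutes / 5.0)
    innov_sd = p["sd"] * np.sqrt(1 - phi**2)

    def _ar1(sd_stat: float) -> np.ndarray:
        ar = np.empty(n)
        ar[0] = rng.normal(0.0, sd_stat)
        eps = rng.normal(0.0, sd_stat * np.sqrt(1 - phi**2), size=n)
        for i in range(1, n):
            ar[i] = phi * ar[i - 1] + eps[i]
        return ar

    temp = (
        p["base"]
        + p["amp"] * np.cos(2 * np.pi * (tod - p["peak_hour"]) / 24.0)
        + _ar1(p["sd"])
    )

    photoperiod = dusk_hour - dawn_hour
    frac = (tod - dawn_hour) / photoperiod
    day_mask = (frac > 0) & (frac < 1)
    irr = np.zeros(n)
    cloud = np.exp(_ar1(p["cloud_sd"]) - 0.5 * p["cloud_sd"] ** 2)
    irr[day_mask] = p["irr_peak"] * np.sin(np.pi * frac[day_mask]) * cloud[day_mask]
    return EnvSeries(times, temp, irr, record_step_minutes=float(step_minutes))


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift ``x`` back by ``lag`` samples, holding the first value at the edge."""
    if lag == 0:
        return x.copy()
    if lag >= len(x):
        raise ValueError(f"lag {lag} exceeds series length {len(x)}")
    out = np.empty_like(x)
    out[:lag] = x[0]
    out[lag:] = x[:-lag]
    return out


def _cascade_latents(params: CascadeParams, h_dawn, zT, zL, gate, rng) -> tuple:
    """Latent log2 levels of the three cascade genes for one grid.

    The clock combines its dawn-phased cosine with a temperature response and
    an intrinsic AR(1) wander (day-to-day amplitude/level fluctuation shared
    by all replicates); both propagate down the cascade.
    """
    n = len(h_dawn)
    eta = np.zeros(n)
    if params.clock_noise_sd > 0:
        phi = params.clock_noise_phi
        eta[0] = rng.normal(0.0, params.clock_noise_sd)
        innov = rng.normal(0.0, params.clock_noise_sd * np.sqrt(1 - phi**2), size=n)
        for i in range(1, n):
            eta[i] = phi * eta[i - 1] + innov[i]
    C = (
        params.clock_amplitude
        * np.cos(2 * np.pi * (h_dawn - params.clock_peak_phase) / 24.0)
        + params.beta_temp_C * zT
        + eta
    )
    S = (
        params.base_S
        + params.beta_temp_S * zT
        + params.beta_irr_S * zL
        + params.beta_up_S * _lagged(C, params.lag1)
    )
    P = params.base_P + params.beta_temp_P * zT + params.beta_up_P * _lagged(S, params.lag2)
    if params.light_gate:
        P = P * gate
    return C, S, P


def _observe(latent, params, rng, grid, name) -> TranscriptSeries:
    obs = latent[:, None] + rng.normal(0.0, params.obs_sd, (len(grid), params.n_replicates))
    return TranscriptSeries(name, grid, np.ma.asarray(2.0**obs))


def gen_cascade_panel(
    envs: list[EnvSeries],
    params: CascadeParams,
    grids: list[SampleGrid],
    gene_names: tuple[str, str, str] = ("CLOCK", "SIG", "PSB"),
) -> list[tuple[TranscriptSeries, TranscriptSeries, TranscriptSeries]]:
    """Cascade across several condition-series with *jointly* z-scored drivers.

    This is the fixture matching a multi-condition regression fit: the
    temperature and irradiance effects operate on z-scores computed over the
    whole panel, so between-condition driver differences carry signal.
    Returns one (clock, mid, downstream) triple per grid.
    """
    tabs = [aggregate_env(e, g, window_minutes=60.0) for e, g in zip(envs, grids)]
    temps = np.concatenate([t["temperature"].to_numpy() for t in tabs])
    irrs = np.concatenate([t["irradiance"].to_numpy() for t in tabs])
    zT_all = _zscore(temps)
    zL_all = _zscore(irrs)
    rng = np.random.default_rng(params.seed)
    out = []
    ofs = 0
    for tab, grid in zip(tabs, grids):
        n = len(grid)
        gate = (tab["irradiance"].to_numpy() > 0).astype(float)
        C, S, P = _cascade_latents(
            params, grid.hours_after_dawn(), zT_all[ofs : ofs + n], zL_all[ofs : ofs + n], gate, rng
        )
        out.append(
            tuple(
                _observe(lat, params, rng, grid, nm)
                for nm, lat in zip(gene_names, (C, S, P))
            )
        )
        ofs += n
    return out


def gen_cascade(
    env: EnvSeries,
    params: CascadeParams,
    grid: SampleGrid,
    gene_names: tuple[str, str, str] = ("CLOCK", "SIG", "PSB"),
) -> tuple[TranscriptSeries, TranscriptSeries, TranscriptSeries]:
    """Simulate the three-gene cascade on a sampling grid.

    Latent log2 levels::

        C(t) = A * cos(2*pi*(h_dawn(t) - peak_phase)/24)
        S(t) = base_S + bT*z(T) + bL*z(L) + bU * C(t - lag1)
        P(t) = [base_P + bTP*z(T) + bUP * S(t - lag2)] * gate(t)

    where the gate (optional) zeroes the downstream latent level at night,
    mirroring light-dependent chloroplast transcription.  Observations add
    replicate-level Gaussian noise on the log2 scale and are returned as
    positive abundances (2**log2-level).
    """
    if grid.timepoints[0] < env.times[0] or grid.timepoints[-1] > env.times[-1]:
        raise ValueError("grid extends outside the environmental record span")
    rng = np.random.default_rng(params.seed)
    tab = aggregate_env(env, grid, window_minutes=60.0)
    zT = _zscore(tab["temperature"].to_numpy())
    zL = _zscore(tab["irradiance"].to_numpy())
    gate = (tab["irradiance"].to_numpy() > 0).astype(float)
    C, S, P = _cascade_latents(params, grid.hours_after_dawn(), zT, zL, gate, rng)
    return tuple(
        _observe(lat, params, rng, grid, nm) for nm, lat in zip(gene_names, (C, S, P))
    )


def cascade_latents(
    env: EnvSeries, params: CascadeParams, grid: SampleGrid
) -> dict[str, np.ndarray]:
    """Noise-free latent log2 levels and z-scored drivers (simulation truth)."""
    noiseless = CascadeParams(**{**params.__dict__, "obs_sd": 0.0, "n_replicates": 1})
    C, S, P = gen_cascade(env, noiseless, grid)
    tab = aggregate_env(env, grid, window_minutes=60.0)
    return {
        "C": np.log2(C.replicate_mean()),
        "S": np.log2(S.replicate_mean()),
        "P": np.log2(P.replicate_mean()),
        "zT": _zscore(tab["temperature"].to_numpy()),
        "zL": _zscore(tab["irradiance"].to_numpy()),
        "temperature": tab["temperature"].to_numpy(),
        "irradiance": tab["irradiance"].to_numpy(),
    }


def gen_coupled_map(
    r_x: float,
    r_y: float,
    beta_xy: float,
    beta_yx: float,
    n: int,
    seed: int = 0,
    burn_in: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unidirectionally or bidirectionally coupled logistic maps.

    Update rule::

        x[t+1] = x[t] * (r_x - r_x*x[t] - beta_xy*y[t])
        y[t+1] = y[t] * (r_y - r_y*y[t] - beta_yx*x[t])

    beta_xy couples y into x's dynamics (y drives x) and vice versa.  Initial
    states are uniform in (0, 1); the first ``burn_in`` steps are discarded.
    A trajectory leaving (0, 1) raises StabilityError with the parameters.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(0.05, 0.95))
    y = float(rng.uniform(0.05, 0.95))
    xs = np.empty(n)
    ys = np.empty(n)
    for t in range(burn_in + n):
        x, y = x * (r_x - r_x * x - beta_xy * y), y * (r_y - r_y * y - beta_yx * x)
        if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
            raise StabilityError(
                f"trajectory escaped (0,1) at step {t}: "
                f"r_x={r_x}, r_y={r_y}, beta_xy={beta_xy}, beta_yx={beta_yx}"
            )
        if t >= burn_in:
            xs[t - burn_in] = x
            ys[t - burn_in] = y
    return xs, ys


def gen_null(series: TranscriptSeries, mode: str, seed: int = 0) -> TranscriptSeries:
    """Negative-control series.

    ``shuffle`` permutes timepoints at random (replicate rows move together);
    ``white`` replaces the data with i.i.d. Gaussian log2 values matching the
    source's log2 mean and variance.
    """
    rng = np.random.default_rng(seed)
    if mode == "shuffle":
        perm = rng.permutation(len(series.grid))
        return TranscriptSeries(series.gene_id, series.grid, series.abundance[perm])
    if mode == "white":
        logs = np.log2(series.abundance.compressed())
        mu, sd = float(logs.mean()), float(logs.std(ddof=0))
        draw = rng.normal(mu, sd, series.abundance.shape)
        return TranscriptSeries(series.gene_id, series.grid, np.ma.asarray(2.0**draw))
    raise ValueError(f"unknown null mode {mode!r}")


def two_season_scenario(
    seed: int = 0,
    params: CascadeParams | None = None,
    n_hours: float = 24.0,
) -> dict[str, dict[str, TranscriptSeries]]:
    """Cool-vs-warm field campaign fixture: one cascade per season.

    Drivers are z-scored jointly across the two seasons, so the seasonal
    temperature contrast carries real signal into the mid and downstream
    genes, mirroring a field campaign spanning contrasting thermal regimes.
    Returns ``{"cool": {"CLOCK": ..., "SIG": ..., "PSB": ...}, "warm": ...}``
    plus the environments under key ``"_env"``.
    """
    rng = np.random.default_rng(seed)
    profiles = ("cool", "warm")
    envs, grids = [], []
    n_days = max(2, int(np.ceil(n_hours / 24.0)) + 1)
    for profile in profiles:
        env_seed = int(rng.integers(2**31 - 1))
        start = dt.datetime(2015, 3 if profile == "cool" else 9, 20, 0, 0)
        envs.append(gen_environment(profile, n_days=n_days, seed=env_seed, start=start))
        grids.append(
            make_diel_grid(
                start + dt.timedelta(hours=6), n_hours=n_hours,
                condition=profile, season=profile,
            )
        )
    p = params or CascadeParams()
    p = CascadeParams(**{**p.__dict__, "seed": int(rng.integers(2**31 - 1))})
    triples = gen_cascade_panel(envs, p, grids)
    out: dict = {"_env": dict(zip(profiles, envs))}
    for profile, (C, S, P) in zip(profiles, triples):
        out[profile] = {"CLOCK": C, "SIG": S, "PSB": P}
    return out


def temp_manipulation_scenario(
    seed: int = 0,
    params: CascadeParams | None = None,
    delta_celsius: float = 4.0,
    n_hours: float = 24.0,
) -> dict[str, dict[str, TranscriptSeries]]:
    """Three temperature treatments (ambient, warmed, cooled) of one site.

    Emulates a field temperature-manipulation experiment: one warm-season
    environment, with constant +/- ``delta_celsius`` offsets applied to the
    temperature that the plants experience; irradiance is shared.  Drivers
    are z-scored jointly across the three treatments.
    """
    rng = np.random.default_rng(seed)
    start = dt.datetime(2016, 9, 20, 0, 0)
    n_days = max(2, int(np.ceil(n_hours / 24.0)) + 1)
    env = gen_environment("warm", n_days=n_days, seed=int(rng.integers(2**31 - 1)), start=start)
    conditions = {"ambient": 0.0, "warmed": +delta_celsius, "cooled": -delta_celsius}
    envs = [
        EnvSeries(env.times, env.temperature + off, env.irradiance, env.record_step_minutes)
        for off in conditions.values()
    ]
    grids = [
        make_diel_grid(start + dt.timedelta(hours=6), n_hours=n_hours,
                       condition=name, season="manip")
        for name in conditions
    ]
    p = params or CascadeParams()
    p = CascadeParams(**{**p.__dict__, "seed": int(rng.integers(2**31 - 1))})
    triples = gen_cascade_panel(envs, p, grids)
    out: dict = {"_env": dict(zip(conditions, envs))}
    for name, (C, S, P) in zip(conditions, triples):
        out[name] = {"CLOCK": C, "SIG": S, "PSB": P}
    return out
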