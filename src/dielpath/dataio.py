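"""Data model and I/O for diel transcript time series.

Transcript abundances are relative quantities normalized to a single midday
reference sample, so they are unitless and strictly positive.  The modeling
scale throughout the package is log2 of that normalized abundance: diel
fold changes in field data span roughly 1.3x to more than 1,000x, which makes
an additive Gaussian treatment on the raw scale untenable.

Time has two coordinate systems: clock (local civil) time, which is primary,
and hours relative to solar dawn, computed on demand from per-day dawn/dusk
metadata.  Environmental loggers record at high frequency (typically 5-min
intervals); transcripts are sampled every couple of hours, so environmental
records are aggregated onto the sampling grid with a trailing mean.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    CoverageError,
    IntegrityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: canonical long-table column order used by readers and writers
TABLE_COLUMNS = ("gene", "condition", "season", "time_iso", "replicate", "value")


@dataclass(frozen=True)
class SampleGrid:
    """Sampling schedule with solar metadata.

    Parameters
    ----------
    timepoints : sequence of datetime
        Strictly increasing clock times of tissue sampling.
    step_minutes : float
        Nominal sampling interval in minutes (> 0).
    dawn_times, dusk_times : mapping date -> datetime
        Solar dawn/dusk per calendar day; every timepoint's date must be
        present in both mappings.
    condition, season : str
        Free-text labels (e.g. ``"sun"``, ``"March"``).
    """

    timepoints: tuple[dt.datetime, ...]
    step_minutes: float
    dawn_times: Mapping[dt.date, dt.datetime]
    dusk_times: Mapping[dt.date, dt.datetime]
    condition: str = ""
    season: str = ""

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if len(tps) == 0:
            raise ValueError("grid needs at least one timepoint")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not self.step_minutes > 0:
            raise ValueError("step_minutes must be positive")
        for t in tps:
            if t.date() not in self.dawn_times or t.date() not in self.dusk_times:
                raise ValueError(f"no dawn/dusk metadata for {t.date()}")

    def __len__(self) -> int:
        return len(self.timepoints)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def hours_from_start(self) -> np.ndarray:
        t0 = self.timepoints[0]
        return np.array([(t - t0).total_seconds() / 3600.0 for t in self.timepoints])

    def time_of_day_hours(self) -> np.ndarray:
        """Clock time-of-day in hours for each timepoint, in [0, 24)."""
        return np.array(
            [t.hour + t.minute / 60.0 + t.second / 3600.0 for t in self.timepoints]
        )

    def hours_after_dawn(self) -> np.ndarray:
        return np.array([hours_after_dawn(self, t) for t in self.timepoints])

    def with_labels(self, condition: str | None = None, season: str | None = None) -> "SampleGrid":
        return replace(
            self,
            condition=self.condition if condition is None else condition,
            season=self.season if season is None else season,
        )


@dataclass
class TranscriptSeries:
    """Replicated relative-abundance time series for one gene and condition.

    ``abundance`` is a ``[timepoint x replicate]`` masked array of positive
    reference-normalized values; masked cells mark replicates missing at a
    timepoint and are skipped by all downstream likelihoods.
    """

    gene_id: str
    grid: SampleGrid
    abundance: np.ma.MaskedArray

    def __post_init__(self) -> None:
        arr = np.ma.masked_invalid(np.ma.asarray(self.abundance, dtype=float))
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != len(self.grid):
            raise ValueError(
                f"abundance rows ({arr.shape[0]}) != grid timepoints ({len(self.grid)})"
            )
        if np.any(arr.compressed() <= 0):
            raise ValueError("abundance values must be strictly positive")
        self.abundance = arr

    @property
    def n_replicates(self) -> int:
        return self.abundance.shape[1]

    @property
    def condition(self) -> str:
        return self.grid.condition

    @property
    def season(self) -> str:
        return self.grid.season

    def replicate_mean(self) -> np.ndarray:
        """Per-timepoint mean abundance over unmasked replicates."""
        return np.asarray(self.abundance.mean(axis=1))

    def log2_replicate_mean(self, floor: float | None = None) -> np.ndarray:
        """Per-timepoint mean of log2 abundance over unmasked replicates."""
        m = log2_matrix(self, floor=floor)
        return np.asarray(np.ma.masked_invalid(m).mean(axis=1))


@dataclass
class EnvSeries:
    """High-frequency temperature / irradiance records."""

    times: tuple[dt.datetime, ...]
    temperature: np.ndarray
    irradiance: np.ndarray
    record_step_minutes: float = 5.0

    def __post_init__(self) -> None:
        self.times = tuple(self.times)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        n = len(self.times)
        if self.temperature.shape != (n,) or self.irradiance.shape != (n,):
            raise ValueError("temperature/irradiance must match times in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# grid helpers


def make_diel_grid(
    start: dt.datetime,
    n_hours: float = 24.0,
    step_minutes: float = 120.0,
    dawn_hour: float = 6.0,
    dusk_hour: float = 18.0,
    condition: str = "",
    season: str = "",
) -> SampleGrid:
    """Regular sampling grid with fixed solar dawn/dusk clock hours.

    The default mirrors a field campaign: 2-h sampling over 24 h inclusive
    (13 timepoints), dawn at 06:00 and dusk at 18:00 every day.
    """
    n = int(round(n_hours * 60.0 / step_minutes)) + 1
    tps = tuple(start + dt.timedelta(minutes=step_minutes * i) for i in range(n))
    days = sorted({t.date() for t in tps})
    dawn = {d: dt.datetime.combine(d, dt.time()) + dt.timedelta(hours=dawn_hour) for d in days}
    dusk = {d: dt.datetime.combine(d, dt.time()) + dt.timedelta(hours=dusk_hour) for d in days}
    return SampleGrid(tps, step_minutes, dawn, dusk, condition=condition, season=season)


def hours_after_dawn(grid: SampleGrid, clock_time: dt.datetime) -> float:
    """Signed hours between ``clock_time`` and its own day's solar dawn.

    Raises ``ValueError`` when ``clock_time`` falls outside the grid span
    (padded by one day so dawn metadata always exists).
    """
    lo, hi = grid.timepoints[0], grid.timepoints[-1]
    if not (lo - dt.timedelta(days=1) <= clock_time <= hi + dt.timedelta(days=1)):
        raise ValueError(f"{clock_time} outside grid span [{lo}, {hi}]")
    day = clock_time.date()
    if day not in grid.dawn_times:
        # fall back to nearest day with metadata (span edges)
        day = min(grid.dawn_times, key=lambda d: abs((d - clock_time.date()).days))
    h = (clock_time - grid.dawn_times[day]).total_seconds() / 3600.0
    # canonical range [-24, 24)
    if h >= 24.0:
        h -= 24.0
    elif h < -24.0:
        h += 24.0
    return h


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, needed: Iterable[str]) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")


def read_timeseries_table(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    sheet: str | int | None = None,
    dawn_hour: float = 6.0,
    dusk_hour: float = 18.0,
    allow_nonpositive: bool = False,
    floor: float | None = None,
) -> list[TranscriptSeries]:
    """Read a long-format transcript table into TranscriptSeries objects.

    Expected columns (renameable through ``schema`` mapping canonical ->
    actual): gene, condition, season, time_iso, replicate, value, plus
    optional dawn_iso / dusk_iso per-row solar metadata.  XLSX input is
    accepted when the path ends in ``.xlsx`` (``sheet`` selects the sheet).

    Returns one series per (gene, condition, season), deterministically
    ordered; a replicate missing at a timepoint yields a masked cell and a
    logged warning.
    """
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        df = pd.read_excel(p, sheet_name=sheet if sheet is not None else 0)
    else:
        df = pd.read_csv(p, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, TABLE_COLUMNS)

    dup = df.duplicated(subset=["gene", "condition", "season", "time_iso", "replicate"])
    if dup.any():
        bad = df.loc[dup, ["gene", "condition", "time_iso", "replicate"]].iloc[0]
        raise IntegrityError(f"duplicated record: {tuple(bad)}")

    vals = pd.to_numeric(df["value"], errors="raise")
    if not allow_nonpositive and (vals <= 0).any():
        raise ValueError(
            "non-positive abundance values present; pass allow_nonpositive=True "
            "with a floor to accept them"
        )
    if allow_nonpositive:
        if floor is None:
            pos = vals[vals > 0]
            floor = float(pos.min()) / 2.0 if len(pos) else 1e-6
        vals = vals.clip(lower=floor)
    df = df.assign(value=vals)
    df["time"] = pd.to_datetime(df["time_iso"])

    has_solar = "dawn_iso" in df.columns and "dusk_iso" in df.columns
    out: list[TranscriptSeries] = []
    for (gene, cond, season), g in sorted(
        df.groupby(["gene", "condition", "season"], sort=True), key=lambda kv: kv[0]
    ):
        times = sorted(g["time"].unique())
        reps = sorted(g["replicate"].unique())
        t_idx = {t: i for i, t in enumerate(times)}
        r_idx = {r: j for j, r in enumerate(reps)}
        arr = np.full((len(times), len(reps)), np.nan)
        for _, row in g.iterrows():
            arr[t_idx[row["time"]], r_idx[row["replicate"]]] = row["value"]
        n_missing = int(np.isnan(arr).sum())
        if n_missing:
            logger.warning(
                "%s/%s/%s: %d missing replicate cell(s) masked", gene, cond, season, n_missing
            )
            warnings.warn(
                f"{gene}/{cond}/{season}: {n_missing} missing replicate cell(s) masked",
                stacklevel=2,
            )
        pydt = [pd.Timestamp(t).to_pydatetime() for t in times]
        if len(pydt) > 1:
            step = min(
                (b - a).total_seconds() / 60.0 for a, b in zip(pydt, pydt[1:])
            )
        else:
            step = 120.0
        days = sorted({t.date() for t in pydt})
        if has_solar:
            dawn, dusk = {}, {}
            for _, row in g.iterrows():
                d = pd.Timestamp(row["time"]).date()
                dawn[d] = pd.Timestamp(row["dawn_iso"]).to_pydatetime()
                dusk[d] = pd.Timestamp(row["dusk_iso"]).to_pydatetime()
        else:
            dawn = {
                d: dt.datetime.combine(d, dt.time()) + dt.timedelta(hours=dawn_hour)
                for d in days
            }
            dusk = {
                d: dt.datetime.combine(d, dt.time()) + dt.timedelta(hours=dusk_hour)
                for d in days
            }
        grid = SampleGrid(tuple(pydt), step, dawn, dusk, condition=str(cond), season=str(season))
        out.append(TranscriptSeries(str(gene), grid, np.ma.masked_invalid(arr)))
    return out


def write_timeseries_table(series: Sequence[TranscriptSeries], path) -> None:
    """Write series to the canonical long CSV (masked cells omitted)."""
    rows = []
    for s in series:
        for i, t in enumerate(s.grid.timepoints):
            d = t.date()
            for j in range(s.n_replicates):
                if np.ma.is_masked(s.abundance[i, j]):
                    continue
                rows.append(
                    {
                        "gene": s.gene_id,
                        "condition": s.condition,
                        "season": s.season,
                        "time_iso": t.isoformat(),
                        "replicate": j + 1,
                        "value": float(s.abundance[i, j]),
                        "dawn_iso": s.grid.dawn_times[d].isoformat(),
                        "dusk_iso": s.grid.dusk_times[d].isoformat(),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_env_table(env: EnvSeries, path) -> None:
    pd.DataFrame(
        {
            "time_iso": [t.isoformat() for t in env.times],
            "temperature": env.temperature,
            "irradiance": env.irradiance,
        }
    ).to_csv(path, index=False)


def read_env_table(path, record_step_minutes: float | None = None) -> EnvSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_iso", "temperature", "irradiance"))
    times = [pd.Timestamp(t).to_pydatetime() for t in pd.to_datetime(df["time_iso"])]
    if record_step_minutes is None:
        record_step_minutes = (
            (times[1] - times[0]).total_seconds() / 60.0 if len(times) > 1 else 5.0
        )
    return EnvSeries(tuple(times), df["temperature"].to_numpy(), df["irradiance"].to_numpy(),
                     record_step_minutes)


# ---------------------------------------------------------------------------
# transforms


def normalize_to_reference(series: TranscriptSeries, reference_value: float) -> TranscriptSeries:
    """Divide all abundances by one positive reference sample's value."""
    if not reference_value > 0:
        raise ValueError("reference_value must be > 0")
    return TranscriptSeries(series.gene_id, series.grid, series.abundance / reference_value)


def aggregate_env(
    env: EnvSeries, grid: SampleGrid, window_minutes: float = 60.0
) -> pd.DataFrame:
    """Trailing-window mean of environmental records at each sample time.

    For each grid timepoint t the mean of records in the half-open window
    (t - window, t] is returned.  Raises CoverageError when a window holds
    no records.
    """
    times = np.array(env.times, dtype="datetime64[s]")
    out_t, out_l = [], []
    for t in grid.timepoints:
        hi = np.datetime64(t, "s")
        lo = hi - np.timedelta64(int(window_minutes * 60), "s")
        sel = (times > lo) & (times <= hi)
        if not sel.any():
            raise CoverageError(f"no environmental records in ({lo}, {hi}]")
        out_t.append(float(env.temperature[sel].mean()))
        out_l.append(float(env.irradiance[sel].mean()))
    return pd.DataFrame(
        {"time": list(grid.timepoints), "temperature": out_t, "irradiance": out_l}
    ).set_index("time")


def log2_matrix(series: TranscriptSeries, floor: float | None = None) -> np.ndarray:
    """log2 abundance matrix with a positivity floor; masked cells -> NaN.

    ``floor`` defaults to half the smallest positive observed value.
    """
    arr = series.abundance
    if floor is None:
        floor = float(arr.compressed().min()) / 2.0
    if not floor > 0:
        raise ValueError("floor must be > 0")
    filled = np.where(arr.mask, np.nan, np.asarray(arr.filled(np.nan)))
    with np.errstate(invalid="ignore"):
        return np.log2(np.fmax(filled, floor))


def check_shared_grid(series: Sequence[TranscriptSeries]) -> SampleGrid:
    """Verify all series share a timepoint layout; return the first grid.

    Grids must agree in timepoint count and in hours-from-start offsets
    (clock dates may differ between conditions sampled on different days).
    """
    g0 = series[0].grid
    h0 = g0.hours_from_start()
    for s in series[1:]:
        h = s.grid.hours_from_start()
        if len(h) != len(h0) or not np.allclose(h, h0):
            raise AlignmentError(
                f"grid of {s.gene_id}/{s.condition} does not align with {series[0].gene_id}/{g0.condition}"
            )
    return g0
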