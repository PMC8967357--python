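"""Hourly weather series: reading, daily-to-hourly downscaling, synthesis.

The simulator runs on an hourly clock of air temperature (degC), shortwave
solar radiation (W m^-2), relative humidity (%), wind speed (m s^-1) and
ambient CO2 (umol mol^-1).  Daily inputs (Tmax/Tmin/solar total) are
downscaled with a standard diurnal scheme: daytime sine between the dawn
minimum and a mid-afternoon maximum, nighttime exponential decay, and solar
radiation distributed as a half-sine over the daylength.  A stochastic
generator emulates two contrasting winter climates -- a humid-subtropical
profile whose winters never approach the frost-damage range, and a
humid-continental profile with recurring hard frost -- so the cold-stress
pathways can be exercised without external datasets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeatherFormatError",
    "WeatherSeries",
    "CO2Trajectory",
    "read_weather",
    "downscale_daily_to_hourly",
    "synthesize_weather",
    "ClimateProfile",
    "PROFILES",
]

HOURLY_COLUMNS = ["timestamp", "T_air", "solar", "RH", "wind", "CO2"]
DAILY_COLUMNS = ["date", "T_max", "T_min", "solar_total", "RH_mean", "wind_mean"]

PEAK_HOUR = 14          # local solar hour of the daily temperature maximum
NIGHT_DECAY = 0.5       # h^-1, nighttime exponential decay rate


class WeatherFormatError(ValueError):
    """Malformed weather input; the message names the first offending row."""


@dataclass
class WeatherSeries:
    """Validated weather table with either hourly or daily cadence."""

    data: pd.DataFrame
    cadence: str = "hourly"   # "hourly" | "daily"

    def __post_init__(self) -> None:
        if self.cadence not in ("hourly", "daily"):
            raise ValueError("cadence must be 'hourly' or 'daily'")
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        if self.cadence == "hourly":
            missing = [c for c in HOURLY_COLUMNS if c not in df.columns]
            if missing:
                raise WeatherFormatError(f"missing column(s): {missing}")
            ts = pd.to_datetime(df["timestamp"])
            if len(ts) > 1:
                deltas = ts.diff().dropna()
                bad = deltas[deltas != pd.Timedelta(hours=1)]
                if len(bad):
                    row = bad.index[0]
                    raise WeatherFormatError(
                        f"row {row}: timestamps must increase at a fixed 1-h step"
                    )
            bad_rh = df.index[(df["RH"] < 0) | (df["RH"] > 100)]
            if len(bad_rh):
                raise WeatherFormatError(
                    f"row {bad_rh[0]}: RH={df.loc[bad_rh[0], 'RH']} outside [0, 100]"
                )
            bad_solar = df.index[df["solar"] < 0]
            if len(bad_solar):
                raise WeatherFormatError(f"row {bad_solar[0]}: negative solar radiation")
            bad_wind = df.index[df["wind"] < 0]
            if len(bad_wind):
                raise WeatherFormatError(f"row {bad_wind[0]}: negative wind speed")
            bad_co2 = df.index[df["CO2"] <= 0]
            if len(bad_co2):
                raise WeatherFormatError(f"row {bad_co2[0]}: non-positive CO2")
        else:
            missing = [c for c in DAILY_COLUMNS if c not in df.columns]
            if missing:
                raise WeatherFormatError(f"missing column(s): {missing}")
            bad = df.index[df["T_max"] < df["T_min"]]
            if len(bad):
                raise WeatherFormatError(f"row {bad[0]}: T_max < T_min")

    def slice_dates(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Hourly rows with start <= date < end; errors name a missing gap."""
        if self.cadence != "hourly":
            raise ValueError("slice_dates requires an hourly series")
        ts = pd.to_datetime(self.data["timestamp"])
        mask = (ts.dt.date >= start) & (ts.dt.date < end)
        out = self.data.loc[mask].reset_index(drop=True)
        expected = (end - start).days * 24
        if len(out) != expected:
            raise ValueError(
                f"weather gap: need {expected} hourly records covering "
                f"[{start}, {end}), found {len(out)}"
            )
        return out

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_weather(path) -> WeatherSeries:
    """Read an hourly or daily weather CSV; cadence is inferred from columns."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(HOURLY_COLUMNS) <= cols:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return WeatherSeries(df[HOURLY_COLUMNS].copy(), cadence="hourly")
    if set(DAILY_COLUMNS) <= cols:
        df["date"] = pd.to_datetime(df["date"]).dt.date
        return WeatherSeries(df[DAILY_COLUMNS].copy(), cadence="daily")
    raise WeatherFormatError(
        f"header {sorted(cols)} matches neither hourly {HOURLY_COLUMNS} "
        f"nor daily {DAILY_COLUMNS} layout"
    )


# --- solar geometry -------------------------------------------------------

def solar_declination(doy) -> np.ndarray:
    """Solar declination (degrees) by day of year."""
    return -23.44 * np.cos(2 * np.pi * (np.asarray(doy) + 10) / 365.0)


def day_bounds(doy, latitude: float):
    """(sunrise, sunset) in local solar hours; clamped for polar cases."""
    decl = np.radians(solar_declination(doy))
    lat = np.radians(latitude)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    half = np.degrees(np.arccos(cos_ws)) / 15.0
    return 12.0 - half, 12.0 + half


def _day_temperature(hours, t_min, t_max, sunrise):
    """Diurnal temperature curve sampled at integer hours.

    The coldest sampled hour (floor of sunrise) carries T_min exactly and
    the 14:00 sample carries T_max exactly, so a daily min/max aggregation
    of the hourly output recovers the inputs.
    """
    rng = t_max - t_min
    h0 = np.floor(sunrise)
    t = np.empty_like(hours, dtype=float)
    rise = (hours >= h0) & (hours <= PEAK_HOUR)
    t[rise] = t_min + rng * np.sin(
        0.5 * np.pi * (hours[rise] - h0) / max(PEAK_HOUR - h0, 1e-9)
    )
    night = hours > PEAK_HOUR
    t[night] = t_min + rng * np.exp(-NIGHT_DECAY * (hours[night] - PEAK_HOUR))
    pre = hours < h0
    t[pre] = t_min + rng * np.exp(-NIGHT_DECAY * (24.0 - PEAK_HOUR + hours[pre]))
    return t


def _day_solar(hours, solar_total_mj, sunrise, sunset):
    """Half-sine hourly solar (W m^-2) integrating to solar_total exactly."""
    mid = hours + 0.5
    w = np.where(
        (mid > sunrise) & (mid < sunset),
        np.sin(np.pi * (mid - sunrise) / max(sunset - sunrise, 1e-9)),
        0.0,
    )
    total_ws = solar_total_mj * 1e6  # J m^-2
    s = w.sum()
    if s <= 0:
        return np.zeros_like(w)
    return w * (total_ws / (s * 3600.0))


def downscale_daily_to_hourly(
    daily: WeatherSeries, latitude: float, co2: float = 400.0
) -> WeatherSeries:
    """Expand a daily series to 24 hourly records per day."""
    if daily.cadence != "daily":
        raise ValueError("input must be a daily-cadence series")
    if len(daily) == 0:
        raise ValueError("empty daily series")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    hours = np.arange(24, dtype=float)
    frames = []
    for _, row in daily.data.iterrows():
        date = row["date"]
        doy = date.timetuple().tm_yday
        sunrise, sunset = day_bounds(doy, latitude)
        t_air = _day_temperature(hours, row["T_min"], row["T_max"], sunrise)
        solar = _day_solar(hours, row["solar_total"], sunrise, sunset)
        frames.append(pd.DataFrame({
            "timestamp": [dt.datetime.combine(date, dt.time(int(h))) for h in hours],
            "T_air": t_air,
            "solar": solar,
            "RH": row["RH_mean"],
            "wind": row["wind_mean"],
            "CO2": co2,
        }))
    return WeatherSeries(pd.concat(frames, ignore_index=True), cadence="hourly")


# --- synthetic climate profiles ------------------------------------------

@dataclass(frozen=True)
class ClimateProfile:
    """Sinusoidal annual climate with AR(1) daily residuals.

    ``amp_winter``/``amp_summer`` are the seasonal depressions/elevations of
    the daily mean temperature about ``t_mean``; the winter amplitude scales
    with the generator's ``severity`` argument.  The warmest day is pinned
    near the end of July (day of year 196).
    """

    name: str
    latitude: float
    t_mean: float
    amp_winter: float
    amp_summer: float
    diurnal_range: float
    t_sigma: float          # sd of AR(1) daily residual, degC
    t_rho: float = 0.7
    transmissivity: float = 0.55
    rh_mean: float = 70.0
    wind_mean: float = 3.0

    def seasonal_mean(self, doy, severity: float = 1.0):
        c = np.cos(2 * np.pi * (np.asarray(doy, dtype=float) - 196.0) / 365.0)
        amp = np.where(c >= 0, self.amp_summer, self.amp_winter * severity)
        return self.t_mean + amp * c


PROFILES = {
    "subtropical": ClimateProfile(
        name="subtropical", latitude=33.3, t_mean=16.0,
        amp_winter=10.0, amp_summer=11.0, diurnal_range=8.0, t_sigma=2.0,
    ),
    "continental": ClimateProfile(
        name="continental", latitude=37.9, t_mean=12.0,
        amp_winter=22.0, amp_summer=14.0, diurnal_range=10.0, t_sigma=4.0,
    ),
}


def _extraterrestrial_mj(doy, latitude: float):
    """Daily top-of-atmosphere solar radiation, MJ m^-2 d^-1."""
    decl = np.radians(solar_declination(doy))
    lat = np.radians(latitude)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    dr = 1 + 0.033 * np.cos(2 * np.pi * np.asarray(doy) / 365.0)
    gsc = 0.0820  # MJ m^-2 min^-1
    return (24 * 60 / np.pi) * gsc * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )


def synthesize_weather(
    profile: str,
    years: int,
    seed: int,
    severity: float = 1.0,
    start_year: int = 2020,
    co2: float = 400.0,
) -> WeatherSeries:
    """Generate an hourly synthetic weather series for a named climate profile.

    Daily mean temperatures follow the profile's seasonal sinusoid plus a
    clipped AR(1) residual; each day is expanded to hours with the same
    diurnal scheme used for downscaling, then re-centred so hourly means
    track the seasonal curve.  Reproducible for a given seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    prof = PROFILES[profile]
    rng = np.random.default_rng(seed)

    start = dt.date(start_year, 1, 1)
    end = dt.date(start_year + years, 1, 1)
    dates = pd.date_range(start, end - dt.timedelta(days=1), freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()

    # AR(1) residual on daily mean temperature, clipped at 3 sd
    eps = rng.normal(0.0, prof.t_sigma * np.sqrt(1 - prof.t_rho**2), size=n)
    resid = np.empty(n)
    resid[0] = rng.normal(0.0, prof.t_sigma)
    for i in range(1, n):
        resid[i] = prof.t_rho * resid[i - 1] + eps[i]
    resid = np.clip(resid, -3 * prof.t_sigma, 3 * prof.t_sigma)
    t_mean_daily = prof.seasonal_mean(doy, severity) + resid

    # solar: clear-sky fraction of extraterrestrial radiation with noise
    ra = _extraterrestrial_mj(doy, prof.latitude)
    tau = np.clip(prof.transmissivity + rng.normal(0.0, 0.12, size=n), 0.2, 0.75)
    solar_total = ra * tau

    rh = np.clip(prof.rh_mean + rng.normal(0.0, 10.0, size=n), 30.0, 100.0)
    wind = np.maximum(np.abs(rng.normal(prof.wind_mean, 1.5, size=n)), 0.1)

    half = prof.diurnal_range / 2.0
    hours = np.arange(24, dtype=float)
    frames = []
    for i, date in enumerate(dates):
        sunrise, sunset = day_bounds(doy[i], prof.latitude)
        t_air = _day_temperature(
            hours, t_mean_daily[i] - half, t_mean_daily[i] + half, sunrise
        )
        # re-centre so the hourly mean equals the daily mean temperature
        t_air = t_air + (t_mean_daily[i] - t_air.mean())
        solar = _day_solar(hours, solar_total[i], sunrise, sunset)
        frames.append(pd.DataFrame({
            "timestamp": [
                dt.datetime.combine(date.date(), dt.time(int(h))) for h in hours
            ],
            "T_air": t_air,
            "solar": solar,
            "RH": rh[i],
            "wind": wind[i],
            "CO2": co2,
        }))
    return WeatherSeries(pd.concat(frames, ignore_index=True), cadence="hourly")


# --- scenario CO2 ---------------------------------------------------------

@dataclass(frozen=True)
class CO2Trajectory:
    """Piecewise-linear CO2 concentration between scenario anchor years."""

    anchors: dict = field(default_factory=lambda: {2020: 412.0, 2100: 412.0})
    scenario: str = "constant"

    def __post_init__(self) -> None:
        years = list(self.anchors)
        if years != sorted(years):
            raise ValueError("anchor years must be strictly increasing")
        if len(set(years)) != len(years):
            raise ValueError("duplicate anchor years")
        if any(v <= 0 for v in self.anchors.values()):
            raise ValueError("CO2 concentrations must be positive")

    def at(self, when) -> float:
        """CO2 (umol mol^-1) at a datetime/date/decimal year; no extrapolation."""
        if isinstance(when, (dt.datetime, dt.date)):
            year_start = dt.date(when.year, 1, 1)
            d = when.date() if isinstance(when, dt.datetime) else when
            ndays = 366 if when.year % 4 == 0 else 365
            t = when.year + (d - year_start).days / ndays
        else:
            t = float(when)
        years = np.array(list(self.anchors), dtype=float)
        vals = np.array(list(self.anchors.values()), dtype=float)
        if not years[0] <= t <= years[-1]:
            raise ValueError(
                f"year {t:.2f} outside anchor range [{years[0]:.0f}, {years[-1]:.0f}]"
            )
        return float(np.interp(t, years, vals))


def co2_at(trajectory: CO2Trajectory, when) -> float:
    return trajectory.at(when)
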