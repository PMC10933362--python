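"""Agro-climatic and soil-derived features.

Climate features summarize the growing season: the standardized Shannon
diversity index (SDI) of daily rainfall (1 = perfectly uniform, 0 = all rain
in one day) and cumulated degree-days above a 5 deg C base for cold-season
crops.  Soil features derived from routine tests: exchangeable acidity from
the SMP buffer pH, cation exchange capacity (CEC) as the sum of exchangeable
cations plus acidity, and base saturation as the cation share of CEC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BASE_TEMP = 5.0  # deg C, cold-crop base


class UndefinedSDIError(ValueError):
    """SDI is undefined: no rainfall, or a single-day season (ln n = 0)."""


@dataclass(frozen=True)
class RainfallSeries:
    """Daily rainfall over a growing season, mm/day."""

    daily_rain: np.ndarray

    def __post_init__(self) -> None:
        rain = np.asarray(self.daily_rain, dtype=float)
        object.__setattr__(self, "daily_rain", rain)
        if rain.ndim != 1 or rain.size < 1:
            raise ValueError("rainfall series must be a non-empty 1-d array")
        if np.any(rain < 0) or not np.all(np.isfinite(rain)):
            raise ValueError("rainfall values must be finite and >= 0")

    @property
    def n(self) -> int:
        return int(self.daily_rain.size)

    @property
    def total(self) -> float:
        return float(self.daily_rain.sum())


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily minimum/maximum temperatures over a season, deg C."""

    daily_tmin: np.ndarray
    daily_tmax: np.ndarray
    base: float = DEFAULT_BASE_TEMP

    def __post_init__(self) -> None:
        tmin = np.asarray(self.daily_tmin, dtype=float)
        tmax = np.asarray(self.daily_tmax, dtype=float)
        object.__setattr__(self, "daily_tmin", tmin)
        object.__setattr__(self, "daily_tmax", tmax)
        if tmin.shape != tmax.shape or tmin.ndim != 1:
            raise ValueError("tmin and tmax must be aligned 1-d arrays")
        if np.any(tmin > tmax):
            raise ValueError("tmin exceeds tmax on some day")


@dataclass(frozen=True)
class SoilTest:
    """One routine soil-test record (0-20 cm composite sample)."""

    pH_water: float
    pH_SMP: float
    clay: float                 # %
    organic_matter: float       # %
    exch_ca: float              # cmolc/dm3
    exch_mg: float              # cmolc/dm3
    exch_k: float               # cmolc/dm3
    exch_acidity: float         # cmolc/dm3
    extractable: dict[str, float] = field(default_factory=dict)  # mg/dm3 (P, K, S, B, Cu, Zn, Mn, Fe)

    @property
    def cec(self) -> float:
        return self.exch_ca + self.exch_mg + self.exch_k + self.exch_acidity

    @property
    def base_saturation(self) -> float:
        cations = self.exch_ca + self.exch_mg + self.exch_k
        if self.cec == 0:
            raise ValueError("CEC is zero; base saturation undefined")
        return 100.0 * cations / self.cec


def sdi(series: RainfallSeries) -> float:
    """Standardized Shannon diversity index of a daily rainfall series.

    ``SDI = -sum p_i ln(p_i) / ln(n)`` with ``p_i`` the daily share of the
    season total and the convention ``0 * ln(0) = 0``.  Lies in [0, 1]:
    1 for perfectly uniform rainfall, 0 when all rain falls on one day.
    """
    if series.n < 2:
        raise UndefinedSDIError("SDI undefined for a single-day season (ln n = 0)")
    total = series.total
    if total <= 0:
        raise UndefinedSDIError("SDI undefined for an all-zero rainfall series")
    p = series.daily_rain / total
    nonzero = p > 0
    entropy = -float(np.sum(p[nonzero] * np.log(p[nonzero])))
    return entropy / float(np.log(series.n))


def degree_days(series: TemperatureSeries) -> float:
    """Cumulated degree-days: ``sum max(0, (tmax+tmin)/2 - base)``, deg C·day."""
    daily_mean = (series.daily_tmin + series.daily_tmax) / 2.0
    return float(np.maximum(0.0, daily_mean - series.base).sum())


def exchangeable_acidity(pH_SMP: float, variant: str = "corrected") -> float:
    """Exchangeable acidity (cmolc/dm3) estimated from the SMP buffer pH.

    Two variants of the calibration are exposed:

    - ``"corrected"`` (default): ``10 ** (7.76 - 1.053 * pH_SMP)``, the
      standard decreasing SMP calibration shape — acidity falls as buffer pH
      rises.
    - ``"literal"``: ``10 * exp(7.76 + 1.053 * pH_SMP)``, the equation as
      published, which increases with pH and contradicts buffer chemistry;
      kept for traceability only.
    """
    if not 3.0 <= pH_SMP <= 8.0:
        warnings.warn(
            f"pH_SMP={pH_SMP} outside the calibrated range [3, 8]", UserWarning, stacklevel=2
        )
    if variant == "corrected":
        return float(10.0 ** (7.76 - 1.053 * pH_SMP))
    if variant == "literal":
        warnings.warn(
            "literal SMP-acidity form increases with pH, contradicting buffer "
            "chemistry; prefer variant='corrected'",
            UserWarning,
            stacklevel=2,
        )
        return float(10.0 * np.exp(7.76 + 1.053 * pH_SMP))
    raise ValueError(f"unknown variant {variant!r}; use 'corrected' or 'literal'")


def cec_and_base_saturation(
    ca: float, mg: float, k: float, acidity: float
) -> tuple[float, float]:
    """CEC (cmolc/dm3) and base saturation (%) from exchangeable cations.

    ``CEC = Ca + Mg + K + acidity``; ``BS = 100 * (Ca + Mg + K) / CEC``.
    """
    if min(ca, mg, k, acidity) < 0:
        raise ValueError("exchangeable quantities must be nonnegative")
    cec = ca + mg + k + acidity
    if cec == 0:
        raise ValueError("CEC is zero; base saturation undefined")
    return cec, 100.0 * (ca + mg + k) / cec


def read_weather_table(path) -> pd.DataFrame:
    """Read a daily weather file: date (ISO-8601), rain_mm, tmin_c, tmax_c."""
    frame = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "rain_mm", "tmin_c", "tmax_c"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"weather table lacks columns: {sorted(missing)}")
    return frame.sort_values("date").reset_index(drop=True)


def season_features(
    weather: pd.DataFrame,
    planting,
    harvest,
    base: float = DEFAULT_BASE_TEMP,
) -> dict[str, float]:
    """Climate feature block for one trial season (inclusive date range)."""
    window = weather[(weather["date"] >= planting) & (weather["date"] <= harvest)]
    if window.empty:
        raise ValueError("no weather records in the requested season window")
    rain = RainfallSeries(window["rain_mm"].to_numpy())
    temps = TemperatureSeries(
        window["tmin_c"].to_numpy(), window["tmax_c"].to_numpy(), base=base
    )
    return {
        "clim_precip_mm": rain.total,
        "clim_sdi": sdi(rain),
        "clim_tmin_c": float(window["tmin_c"].min()),
        "clim_tmax_c": float(window["tmax_c"].max()),
        "clim_degree_days": degree_days(temps),
        "clim_season_days": float(rain.n),
        "clim_planting_doy": float(pd.Timestamp(planting).dayofyear),
    }
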