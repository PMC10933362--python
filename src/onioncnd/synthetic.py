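"""Synthetic multi-environment onion fertilizer-trial generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised and validated without the original trial database:

- 34 trials (26 N, 5 K, 3 P) of ~35 plots each (~1190 plot-seasons), each
  trial a dose gradient on its focal nutrient with four replicate blocks;
- cultivar-specific tissue ionomes drawn logistic-normally: Gaussian in clr
  space around published cultivar centres, projected onto the sum-zero
  hyperplane and back-transformed to concentrations closed to 1000 g/kg;
- a latent balanced/imbalanced state per plot: imbalanced specimens carry a
  ±1.0 clr shift on S (onion's most diagnostic nutrient; roughly a 2.5-fold
  excess or shortage in tissue S) and pay a fixed yield penalty — the
  tissue→yield coupling that makes balance classification, true-negative
  selection and standards recovery testable;
- bulb yield = cultivar intercept + quadratic-plateau response to the
  split-N dose + centered linear terms in soil S and micronutrients −
  imbalance penalty + Gaussian noise, truncated at zero;
- daily weather per trial (dry-day/gamma rainfall mixture, sinusoidal
  temperatures) summarized into the climate feature block;
- 13% of the numeric soil/climate cells masked completely at random (never
  the target, doses, tissue tests or categorical variables; plots lacking
  tissue analyses are treated as excluded from the study population).

The generating parameters are returned verbatim (``truth``) so recovery
tests can compare estimates against them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .climate_soil import RainfallSeries, TemperatureSeries, degree_days, sdi
from .compositions import DEFAULT_KAPPA, NUTRIENTS, PARTS, ClrVector, Composition, clr_back_transform
from .feature_table import (
    CLIMATE_COLUMNS,
    SOIL_COLUMNS,
    TISSUE_COLUMNS,
    TrialObservation,
    frame_to_observations,
    observations_to_frame,
)

#: Columns eligible for missing-value injection.  Tissue tests are kept
#: complete: specimens lacking tissue analyses were dropped from the study
#: population, so the missingness lives in the soil and climate records.
MASKABLE_COLUMNS = SOIL_COLUMNS + CLIMATE_COLUMNS

_MUNICIPALITIES = ("Ituporanga", "Atalanta", "Cacador", "Lebon Regis")
#: Transplanted crops in Ituporanga/Atalanta, direct-seeded in Cacador/Lebon Regis.
_ESTABLISHMENT = {
    "Ituporanga": "transplant",
    "Atalanta": "transplant",
    "Cacador": "direct-seed",
    "Lebon Regis": "direct-seed",
}
_SPLIT_SCHEDULES = {
    "transplant": (0.30, 0.40, 0.30),
    "direct-seed": (0.20, 0.30, 0.30, 0.20),
}
_PREVIOUS_CROPS = ("black oat", "millet", "maize", "tobacco", "sweet potato", "velvet bean")
_TILLAGE = ("conventional", "no-till")


def _default_centers() -> dict[str, np.ndarray]:
    return {
        cultivar: reference.reference_clr_midpoints(cultivar).values.copy()
        for cultivar in reference.REFERENCE_CULTIVARS
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic trial set."""

    seed: int = 0
    n_trials: dict[str, int] = field(default_factory=lambda: {"N": 26, "K": 5, "P": 3})
    plots_per_trial: int = 35
    dose_levels: int = 9
    blocks: int = 4
    dose_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"N": (0.0, 370.0), "K": (0.0, 667.0), "P": (0.0, 349.0)}
    )
    #: doses of the non-focal nutrients, kg/ha (state recommendations).
    fixed_doses: dict[str, float] = field(
        default_factory=lambda: {"N": 120.0, "P": 100.0, "K": 150.0}
    )
    #: all plots managed at the recommended split-N dose, no gradients
    #: (the balanced-management scenario for classification and standards).
    uniform_management: bool = False

    # tissue model
    cultivar_centers: dict[str, np.ndarray] = field(default_factory=_default_centers)
    clr_sd: float = 0.15
    imbalance_prob: float = 0.35
    imbalance_clr_shift: float = 1.0    # applied to S, sign random
    kappa: float = DEFAULT_KAPPA

    # yield model (kg/ha)
    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "Caete": 34000.0,
            "Mulata": 40000.0,
            "Omega": 37000.0,
            "SCS373 Valessul": 32000.0,
        }
    )
    n_optimum: float = 160.0            # kg N/ha at the plateau knot
    n_plateau_gain: float = 22000.0     # kg/ha gained at/beyond the optimum
    soil_coefs: dict[str, float] = field(
        default_factory=lambda: {"s": 60.0, "b": 2000.0, "zn": 150.0, "mn": 50.0, "fe": -20.0}
    )
    soil_refs: dict[str, float] = field(
        default_factory=lambda: {"s": 20.0, "b": 1.0, "zn": 4.0, "mn": 10.0, "fe": 30.0}
    )
    imbalance_penalty: float = 16000.0  # kg/ha lost by imbalanced specimens
    noise_sd: float = 3000.0            # kg/ha

    # weather process
    transplant_season_days: int = 120
    seeded_season_days: int = 150
    dry_day_prob: float = 0.45
    rain_gamma_shape: float = 0.8
    rain_gamma_scale: float = 12.0      # mm
    temp_mean: float = 16.0             # deg C
    temp_amplitude: float = 5.0
    temp_noise_sd: float = 1.5

    missing_rate: float = 0.13

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.clr_sd <= 0 or self.noise_sd < 0:
            raise ValueError("spreads must be positive")
        if not self.uniform_management and self.plots_per_trial < self.dose_levels:
            raise ValueError(
                f"plots_per_trial={self.plots_per_trial} < dose_levels={self.dose_levels}"
            )
        for cultivar, center in self.cultivar_centers.items():
            center = np.asarray(center, dtype=float)
            if center.shape != (len(PARTS),):
                raise ValueError(f"clr centre for {cultivar!r} must have {len(PARTS)} parts")
            self.cultivar_centers[cultivar] = center

    @classmethod
    def balanced_management(cls, seed: int = 0, plots_per_trial: int = 50) -> "GeneratorConfig":
        """Scenario for balance classification and standards derivation.

        Every plot receives the recommended split-N dose (no gradients) and
        tissue records are complete — class membership at the 50 Mg/ha
        cutoff is then governed by cultivar and nutritional balance, the
        structure the classification stage is meant to resolve.
        """
        return cls(
            seed=seed,
            plots_per_trial=plots_per_trial,
            uniform_management=True,
            missing_rate=0.0,
        )

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["cultivar_centers"] = {c: v.tolist() for c, v in self.cultivar_centers.items()}
        return raw


@dataclass
class SyntheticTrialSet:
    """Generated observations plus the generating truth."""

    observations: list[TrialObservation]
    frame: pd.DataFrame                 # delimited-text layout, with injected NaNs
    truth: dict

    def write(self, path, truth_path=None) -> None:
        self.frame.to_csv(path, index=False)
        if truth_path is not None:
            payload = {
                "config": self.truth["config"].to_dict(),
                "imbalanced": [bool(v) for v in self.truth["imbalanced"]],
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=1)


def quadratic_plateau(dose: float, optimum: float, gain: float) -> float:
    """Quadratic-plateau response: rises to ``gain`` at ``optimum``, flat after.

    Chosen over a pure quadratic, whose descending arm past the optimum
    overstates the cost of extra N and inflates dose recommendations.
    """
    t = min(float(dose) / optimum, 1.0) if optimum > 0 else 1.0
    return gain * (2.0 * t - t * t)


def _draw_clr(
    center: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    shift_part: int | None = None,
    shift: float = 0.0,
) -> np.ndarray:
    z = center + sd * rng.standard_normal(center.size)
    if shift_part is not None:
        z[shift_part] += shift
    return z - z.mean()   # project onto the sum-zero hyperplane


def generate_tissue(
    cultivar: str,
    n: int,
    config: GeneratorConfig,
    seed: int,
) -> list[Composition]:
    """Draw n balanced tissue compositions for a cultivar (logistic-normal)."""
    if cultivar not in config.cultivar_centers:
        raise KeyError(f"unknown cultivar {cultivar!r}; have {sorted(config.cultivar_centers)}")
    rng = np.random.default_rng(int(seed) % (2**31))
    center = config.cultivar_centers[cultivar]
    out = []
    for _ in range(n):
        z = _draw_clr(center, config.clr_sd, rng)
        out.append(clr_back_transform(ClrVector(PARTS, z), kappa=config.kappa))
    return out


def generate_yield(
    cultivar: str,
    n_dose: float,
    soil: Mapping[str, float],
    config: GeneratorConfig,
    imbalanced: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Marketable bulb yield, kg/ha; deterministic when ``rng`` is None."""
    value = config.intercepts[cultivar]
    value += quadratic_plateau(n_dose, config.n_optimum, config.n_plateau_gain)
    for key, coef in config.soil_coefs.items():
        value += coef * (float(soil[key]) - config.soil_refs[key])
    if imbalanced:
        value -= config.imbalance_penalty
    if rng is not None:
        value += rng.normal(0.0, config.noise_sd)
    return max(0.0, float(value))


def generate_weather(
    season_length: int,
    config: GeneratorConfig,
    seed: int,
    planting_doy: int = 200,
) -> tuple[RainfallSeries, TemperatureSeries]:
    """Daily rainfall and temperature series for one growing season."""
    if season_length < 30:
        raise ValueError("season_length must be >= 30 days")
    rng = np.random.default_rng(int(seed) % (2**31))
    return _weather(season_length, config, rng, planting_doy)


def _weather(
    season_length: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    planting_doy: int,
) -> tuple[RainfallSeries, TemperatureSeries]:
    wet = rng.random(season_length) >= config.dry_day_prob
    amounts = rng.gamma(config.rain_gamma_shape, config.rain_gamma_scale, season_length)
    rain = np.where(wet, amounts, 0.0)
    if not np.any(rain > 0):        # degenerate dry season: one token shower
        rain[rng.integers(season_length)] = config.rain_gamma_scale
    doy = planting_doy + np.arange(season_length)
    seasonal = config.temp_mean + config.temp_amplitude * np.sin(2 * np.pi * (doy - 280) / 365.0)
    tmean = seasonal + rng.normal(0.0, config.temp_noise_sd, season_length)
    half_range = rng.uniform(1.5, 3.5, season_length)
    return (
        RainfallSeries(rain),
        TemperatureSeries(tmean - half_range, tmean + half_range),
    )


def _trial_soil(rng: np.random.Generator) -> dict[str, float]:
    """One trial-level soil test draw (Cambisol-like ranges)."""
    ph = float(np.clip(rng.normal(5.8, 0.45), 4.5, 7.2))
    exch_ca = float(np.clip(rng.normal(8.0, 2.0), 2.0, 15.0))
    exch_mg = float(np.clip(rng.normal(4.0, 1.0), 1.0, 8.0))
    exch_k = float(np.clip(rng.normal(0.5, 0.15), 0.1, 1.2))
    acidity = float(np.exp(rng.normal(1.1, 0.5)))
    cec = exch_ca + exch_mg + exch_k + acidity
    return {
        "ph": ph,
        "clay_pct": float(np.clip(rng.normal(50.0, 12.0), 15.0, 80.0)),
        "om_pct": float(np.clip(rng.normal(4.2, 1.1), 1.5, 8.0)),
        "cec": cec,
        "base_sat": 100.0 * (exch_ca + exch_mg + exch_k) / cec,
        "ca": exch_ca,
        "mg": exch_mg,
        "p": float(np.exp(rng.normal(np.log(10.0), 0.6))),
        "k": float(np.clip(rng.normal(250.0, 80.0), 40.0, 600.0)),
        "s": float(np.exp(rng.normal(np.log(20.0), 0.4))),
        "b": float(np.clip(rng.normal(1.0, 0.2), 0.3, 2.0)),
        "cu": float(np.exp(rng.normal(np.log(4.0), 0.7))),
        "zn": float(np.exp(rng.normal(np.log(4.0), 0.6))),
        "mn": float(np.exp(rng.normal(np.log(10.0), 0.7))),
        "fe": float(np.exp(rng.normal(np.log(30.0), 0.4))),
    }


def generate_trials(config: GeneratorConfig) -> SyntheticTrialSet:
    """Generate the full multi-environment trial set under ``config``."""
    rng = np.random.default_rng(int(config.seed) % (2**31))
    cultivars = sorted(config.cultivar_centers)
    s_index = PARTS.index("S")

    observations: list[TrialObservation] = []
    imbalanced_flags: list[bool] = []
    trial_counter = 0
    for nutrient in ("N", "K", "P"):
        for _ in range(config.n_trials.get(nutrient, 0)):
            trial_id = f"{nutrient}{trial_counter:03d}"
            cultivar = cultivars[trial_counter % len(cultivars)]
            municipality = _MUNICIPALITIES[int(rng.integers(len(_MUNICIPALITIES)))]
            establishment = _ESTABLISHMENT[municipality]
            schedule = _SPLIT_SCHEDULES[establishment]
            tillage = _TILLAGE[int(rng.integers(2))]
            previous_crop = _PREVIOUS_CROPS[int(rng.integers(len(_PREVIOUS_CROPS)))]
            year = int(rng.integers(2007, 2021))
            season_days = (
                config.transplant_season_days
                if establishment == "transplant"
                else config.seeded_season_days
            )
            planting_doy = int(rng.integers(180, 241))
            rain, temps = _weather(season_days, config, rng, planting_doy)
            climate = {
                "clim_precip_mm": rain.total,
                "clim_sdi": sdi(rain),
                "clim_tmin_c": float(temps.daily_tmin.min()),
                "clim_tmax_c": float(temps.daily_tmax.max()),
                "clim_degree_days": degree_days(temps),
                "clim_season_days": float(season_days),
                "clim_planting_doy": float(planting_doy),
            }
            soil = _trial_soil(rng)

            if config.uniform_management:
                doses = np.full(config.plots_per_trial, config.n_optimum)
                focal = "N"
            else:
                lo, hi = config.dose_ranges[nutrient]
                levels = np.linspace(lo, hi, config.dose_levels)
                doses = np.tile(levels, config.blocks)[: config.plots_per_trial]
                focal = nutrient

            for plot, dose in enumerate(doses):
                plot_doses = dict(config.fixed_doses)
                plot_doses[focal] = float(dose)
                if config.uniform_management:
                    plot_doses["N"] = config.n_optimum
                imbalanced = bool(rng.random() < config.imbalance_prob)
                shift = (
                    config.imbalance_clr_shift * (1 if rng.random() < 0.5 else -1)
                    if imbalanced
                    else 0.0
                )
                z = _draw_clr(
                    config.cultivar_centers[cultivar],
                    config.clr_sd,
                    rng,
                    shift_part=s_index if imbalanced else None,
                    shift=shift,
                )
                tissue = clr_back_transform(ClrVector(PARTS, z), kappa=config.kappa)
                y = generate_yield(
                    cultivar, plot_doses["N"], soil, config, imbalanced=imbalanced, rng=rng
                )
                observations.append(
                    TrialObservation(
                        trial_id=trial_id,
                        year=year,
                        municipality=municipality,
                        cultivar=cultivar,
                        establishment=establishment,
                        tillage=tillage,
                        previous_crop=previous_crop,
                        n_dose=plot_doses["N"],
                        p_dose=plot_doses["P"],
                        k_dose=plot_doses["K"],
                        split_schedule=schedule,
                        soil=soil,
                        tissue=tissue,
                        climate=climate,
                        yield_kg_ha=y,
                    )
                )
                imbalanced_flags.append(imbalanced)
            trial_counter += 1

    complete = observations_to_frame(observations)
    masked = complete.copy()
    if config.missing_rate > 0:
        eligible = [c for c in MASKABLE_COLUMNS if c in masked.columns]
        mask = rng.random((len(masked), len(eligible))) < config.missing_rate
        block = masked[eligible].to_numpy(dtype=float)
        block[mask] = np.nan
        masked[eligible] = block
        observations = frame_to_observations(masked)

    truth = {
        "config": config,
        "imbalanced": imbalanced_flags,
        "clr_centers": {c: v.copy() for c, v in config.cultivar_centers.items()},
        "complete_frame": complete,
    }
    return SyntheticTrialSet(observations=observations, frame=masked, truth=truth)
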