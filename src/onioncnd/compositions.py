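"""Compositional-data engine for tissue ionomes.

Tissue nutrient concentrations are parts of a composition closed to the
measurement unit (kappa = 1000 g/kg for dry tissue).  The complement
``Fv = kappa - sum(nutrients)`` (the *filling value*: water of constitution,
C, H, O and everything not assayed) closes every specimen to kappa, so the
full D-part vector lives on the simplex and is analysed through the centered
log-ratio (clr) transform

    clr_i = ln(x_i / G),    G = (prod_j x_j)^(1/D),

which maps the simplex isometrically onto the sum-zero hyperplane of R^D.
Within that space ordinary Euclidean statistics are unbiased: per-cultivar
means/SDs of clr vectors define nutrient standards, the Euclidean distance
between clr vectors measures compositional proximity, and standardized
deviations from the standard are nutrient balance indices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical nutrient order used across the whole package (macro, then micro).
NUTRIENTS: tuple[str, ...] = ("N", "P", "K", "Ca", "Mg", "S", "B", "Cu", "Zn", "Mn", "Fe")

#: Label of the filling value, always the last part of the closed composition.
FV_LABEL = "Fv"

#: Full part order of a closed composition (D = 12 parts).
PARTS: tuple[str, ...] = NUTRIENTS + (FV_LABEL,)

#: Measurement unit for dry-tissue concentrations, g/kg.
DEFAULT_KAPPA = 1000.0


class CompositionError(ValueError):
    """A vector of concentrations cannot form a valid closed composition."""


class ClosureViolationError(CompositionError):
    """Concentrations meet or exceed the measurement unit kappa."""


class IncompatibleVectorsError(ValueError):
    """Two clr vectors do not share the same part labels."""


class InsufficientDataError(ValueError):
    """Too few specimens to fit a nutrient standard."""


class DegenerateStandardError(ValueError):
    """A nutrient standard has zero spread on some part."""


@dataclass(frozen=True)
class Composition:
    """A closed tissue composition: nutrient concentrations plus filling value.

    Parameters
    ----------
    labels : tuple of str
        Nutrient names in canonical order (filling value excluded).
    concentrations : ndarray
        Strictly positive concentrations, g/kg, aligned with ``labels``.
    kappa : float
        Measurement unit the composition is closed to, g/kg.
    """

    labels: tuple[str, ...]
    concentrations: np.ndarray
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "labels", tuple(self.labels))
        if conc.shape != (len(self.labels),):
            raise CompositionError("labels and concentrations are misaligned")
        if not np.all(np.isfinite(conc)):
            raise CompositionError("non-finite concentration")
        for name, value in zip(self.labels, conc):
            if value <= 0:
                raise CompositionError(f"non-positive concentration for part {name!r}")
        if conc.sum() >= self.kappa:
            raise ClosureViolationError(
                f"concentrations sum to {conc.sum():.3f} >= kappa={self.kappa:.3f}"
            )

    @property
    def fv(self) -> float:
        """Filling value, g/kg: the complement closing the vector to kappa."""
        return self.kappa - float(self.concentrations.sum())

    @property
    def part_labels(self) -> tuple[str, ...]:
        return self.labels + (FV_LABEL,)

    def parts(self) -> np.ndarray:
        """All D parts including the filling value, summing exactly to kappa."""
        return np.append(self.concentrations, self.fv)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.concentrations.tolist()))

    def __getitem__(self, part: str) -> float:
        if part == FV_LABEL:
            return self.fv
        return float(self.concentrations[self.labels.index(part)])


@dataclass(frozen=True)
class ClrVector:
    """The centered log-ratio image of a composition (dimensionless)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.shape != (len(self.labels),):
            raise IncompatibleVectorsError("labels and values are misaligned")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite clr value")

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.labels.index(part)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values.tolist()))


@dataclass(frozen=True)
class NutrientStandard:
    """Per-cultivar clr nutrient standard with back-transformed centroid.

    ``ci_low``/``ci_high`` are two-sided Student-t confidence bounds on the
    per-part clr mean at level ``1 - alpha``; ``centroid`` is the clr mean
    back-transformed to concentrations at the standard's kappa.
    """

    cultivar: str
    labels: tuple[str, ...]
    clr_mean: np.ndarray
    clr_sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alpha: float
    n: int
    centroid: Composition
    degenerate: bool = False

    def mean_vector(self) -> ClrVector:
        return ClrVector(self.labels, self.clr_mean)


def close_composition(
    concentrations: Mapping[str, float] | Sequence[float],
    kappa: float = DEFAULT_KAPPA,
    labels: Sequence[str] = NUTRIENTS,
) -> Composition:
    """Close nutrient concentrations to the measurement unit with a filling value.

    Parameters
    ----------
    concentrations : mapping or sequence
        Nutrient concentrations in g/kg.  A mapping is reordered to the
        canonical label order; a sequence must already follow ``labels``.
    kappa : float
        Measurement unit, g/kg (default 1000 for dry tissue).

    Returns
    -------
    Composition
        With ``fv = kappa - sum(concentrations) > 0`` as the implicit last part.
    """
    if isinstance(concentrations, Mapping):
        missing = [p for p in labels if p not in concentrations]
        if missing:
            raise CompositionError(f"missing parts: {missing}")
        values = [float(concentrations[p]) for p in labels]
    else:
        values = [float(v) for v in concentrations]
    return Composition(tuple(labels), np.asarray(values), kappa=kappa)


def clr_transform(comp: Composition) -> ClrVector:
    """Centered log-ratio transform of a closed composition.

    Each part (including the filling value) is log-divided by the geometric
    mean over all D parts; the result sums to zero.
    """
    parts = comp.parts()
    log_parts = np.log(parts)
    values = log_parts - log_parts.mean()
    return ClrVector(comp.part_labels, values)


def clr_back_transform(
    clr: ClrVector | Sequence[float],
    kappa: float = DEFAULT_KAPPA,
    labels: Sequence[str] | None = None,
) -> Composition:
    """Back-transform clr values to concentrations closed to kappa.

    ``x_i = kappa * exp(clr_i) / sum_j exp(clr_j)``.  The input need not sum
    to zero — closure absorbs any constant offset — but a warning is logged
    when the departure exceeds 1e-6 since valid clr vectors are sum-zero.
    """
    if isinstance(clr, ClrVector):
        values = clr.values
        part_labels = clr.labels
    else:
        values = np.asarray(clr, dtype=float)
        part_labels = tuple(labels) if labels is not None else PARTS
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite clr value in back-transform input")
    total = float(values.sum())
    if abs(total) > 1e-6:
        logger.warning("clr input sums to %.3g (expected 0); closure will normalize", total)
    # subtract max for numerical stability before exponentiation
    ex = np.exp(values - values.max())
    parts = kappa * ex / ex.sum()
    if part_labels[-1] != FV_LABEL:
        raise IncompatibleVectorsError("last part of a clr vector must be the filling value")
    return Composition(tuple(part_labels[:-1]), parts[:-1], kappa=kappa)


def clr_distance(a: ClrVector, b: ClrVector) -> float:
    """Euclidean (Aitchison) distance between two clr vectors."""
    if a.labels != b.labels:
        raise IncompatibleVectorsError(f"label mismatch: {a.labels} vs {b.labels}")
    return float(np.sqrt(np.sum((a.values - b.values) ** 2)))


def fit_standard(
    specimens: Sequence[ClrVector],
    cultivar: str,
    alpha: float = 0.01,
    kappa: float = DEFAULT_KAPPA,
) -> NutrientStandard:
    """Fit a cultivar nutrient standard from balanced high-yield specimens.

    Per-part sample mean and SD of the clr vectors; two-sided Student-t
    confidence interval ``mean ± t_{1-alpha/2, n-1} * SD/sqrt(n)``; centroid
    is the back-transformed mean.

    Raises
    ------
    InsufficientDataError
        Fewer than two specimens.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if len(specimens) < 2:
        raise InsufficientDataError(
            f"need >= 2 specimens to fit a standard for {cultivar!r}, got {len(specimens)}"
        )
    labels = specimens[0].labels
    for s in specimens[1:]:
        if s.labels != labels:
            raise IncompatibleVectorsError("specimens carry different part labels")
    matrix = np.vstack([s.values for s in specimens])
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    degenerate = bool(np.any(sd == 0))
    if degenerate:
        warnings.warn(
            f"standard for {cultivar!r} has zero clr variance on "
            f"{[labels[i] for i in np.flatnonzero(sd == 0)]}; CI collapses to the mean",
            UserWarning,
            stacklevel=2,
        )
    half = stats.t.ppf(1 - alpha / 2, df=n - 1) * sd / math.sqrt(n)
    centroid = clr_back_transform(ClrVector(labels, mean), kappa=kappa)
    return NutrientStandard(
        cultivar=cultivar,
        labels=labels,
        clr_mean=mean,
        clr_sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        alpha=alpha,
        n=n,
        centroid=centroid,
        degenerate=degenerate,
    )


def nutrient_indices(specimen: ClrVector, std: NutrientStandard) -> dict[str, float]:
    """Standardized nutrient balance indices ``I_i = (clr_i - clr*_i) / SD*_i``.

    Positive values flag relative excess, negative values relative shortage
    of the part against the cultivar standard.
    """
    if specimen.labels != std.labels:
        raise IncompatibleVectorsError("specimen and standard labels differ")
    zero_sd = np.flatnonzero(std.clr_sd == 0)
    if zero_sd.size:
        raise DegenerateStandardError(
            f"standard for {std.cultivar!r} has zero SD on "
            f"{[std.labels[i] for i in zero_sd]}"
        )
    indices = (specimen.values - std.clr_mean) / std.clr_sd
    return dict(zip(std.labels, indices.tolist()))


def nearest_balanced_neighbors(
    specimen: ClrVector,
    bank: Sequence[ClrVector],
    k: int = 5,
) -> list[tuple[int, float]]:
    """The k reference specimens compositionally closest to the diagnosed one.

    Returns ``(bank index, distance)`` pairs sorted by ascending Euclidean
    clr distance; ties resolve to the earlier bank entry.
    """
    if len(bank) == 0:
        raise ValueError("reference bank is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    distances = [clr_distance(specimen, member) for member in bank]
    order = np.argsort(distances, kind="stable")[: min(k, len(bank))]
    return [(int(i), float(distances[i])) for i in order]


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

def read_tissue_table(path, kappa: float = DEFAULT_KAPPA) -> list[Composition]:
    """Read a tissue table (CSV, header row, canonical nutrient columns, g/kg)."""
    frame = pd.read_csv(path)
    missing = [p for p in NUTRIENTS if p not in frame.columns]
    if missing:
        raise CompositionError(f"tissue table lacks columns: {missing}")
    return [
        close_composition({p: row[p] for p in NUTRIENTS}, kappa=kappa)
        for _, row in frame.iterrows()
    ]


def standards_to_frame(standards: Iterable[NutrientStandard]) -> pd.DataFrame:
    """Flatten nutrient standards to a long table: one row per cultivar x part."""
    rows = []
    for std in standards:
        centroid_parts = std.centroid.parts()
        for i, part in enumerate(std.labels):
            rows.append(
                {
                    "cultivar": std.cultivar,
                    "part": part,
                    "ci_low": std.ci_low[i],
                    "ci_high": std.ci_high[i],
                    "clr_mean": std.clr_mean[i],
                    "clr_sd": std.clr_sd[i],
                    "centroid_g_kg": centroid_parts[i],
                    "n": std.n,
                    "alpha": std.alpha,
                }
            )
    return pd.DataFrame(rows)


def write_standards(standards: Iterable[NutrientStandard], path) -> None:
    standards_to_frame(standards).to_csv(path, index=False)
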