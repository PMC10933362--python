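"""Assemble trial observations into an analyzable feature matrix.

One row per plot-season.  Five feature groups mirror the trial database:
climate (season summaries), management (cultivar, establishment, tillage,
previous crop, municipality), soil tests, tissue tests, and fertilization
(N-P-K doses and the split count).  Categorical features are integer-encoded
against a stored codebook (tree ensembles split on the codes natively, so no
one-hot expansion), missing cells are filled by iterative random-forest
imputation, and train/test partitions are stratified on the categorical
strata (cultivar x establishment x municipality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .compositions import NUTRIENTS, Composition

CATEGORICAL_COLUMNS = ("cultivar", "establishment", "tillage", "previous_crop", "municipality")
FERTILIZATION_COLUMNS = ("n_dose", "p_dose", "k_dose", "n_split_count")
SOIL_COLUMNS = (
    "soil_ph", "soil_clay_pct", "soil_om_pct", "soil_cec", "soil_base_sat",
    "soil_p", "soil_k", "soil_ca", "soil_mg", "soil_s",
    "soil_b", "soil_cu", "soil_zn", "soil_mn", "soil_fe",
)
TISSUE_COLUMNS = tuple(f"tissue_{p}" for p in NUTRIENTS)
CLIMATE_COLUMNS = (
    "clim_precip_mm", "clim_sdi", "clim_tmin_c", "clim_tmax_c",
    "clim_degree_days", "clim_season_days", "clim_planting_doy",
)

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "climate": CLIMATE_COLUMNS,
    "management": CATEGORICAL_COLUMNS,
    "soil": SOIL_COLUMNS,
    "tissue": TISSUE_COLUMNS,
    "fertilization": FERTILIZATION_COLUMNS,
}

POOLED_STRATUM = "_pooled"
TARGET_COLUMN = "yield_kg_ha"


@dataclass(frozen=True)
class TrialObservation:
    """One plot-season record from a fertilizer trial."""

    trial_id: str
    year: int
    municipality: str
    cultivar: str
    establishment: str          # "transplant" | "direct-seed"
    tillage: str
    previous_crop: str
    n_dose: float               # kg N/ha, split-applied
    p_dose: float               # kg P/ha
    k_dose: float               # kg K/ha
    split_schedule: tuple[float, ...]   # N application fractions, sum to 1
    soil: Mapping[str, float] = field(default_factory=dict)
    tissue: Mapping[str, float] | Composition | None = None
    climate: Mapping[str, float] = field(default_factory=dict)
    yield_kg_ha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_dose", "p_dose", "k_dose"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.yield_kg_ha < 0:
            raise ValueError("yield must be >= 0")
        if self.split_schedule:
            total = float(sum(self.split_schedule))
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"split fractions sum to {total}, expected 1")

    @property
    def n_split_count(self) -> int:
        return len(self.split_schedule)

    def tissue_dict(self) -> dict[str, float]:
        if self.tissue is None:
            return {p: np.nan for p in NUTRIENTS}
        if isinstance(self.tissue, Composition):
            return self.tissue.as_dict()
        return {p: float(self.tissue.get(p, np.nan)) for p in NUTRIENTS}


@dataclass
class FeatureMatrix:
    """Encoded feature matrix with target, strata and missingness bookkeeping."""

    X: pd.DataFrame
    target: pd.Series
    strata: pd.Series
    missing_mask: pd.DataFrame
    codebook: dict[str, list[str]]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.X) != len(self.target) or len(self.X) != len(self.strata):
            raise ValueError("X, target and strata must have equal length")
        if list(self.X.columns) != list(self.missing_mask.columns):
            raise ValueError("missing mask misaligned with X")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def has_missing(self) -> bool:
        return bool(self.X.isna().any().any())

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        """Restrict to a column subset, keeping target/strata/codebook."""
        unknown = [c for c in columns if c not in self.X.columns]
        if unknown:
            raise KeyError(f"unknown columns: {unknown}")
        cols = list(columns)
        return FeatureMatrix(
            X=self.X[cols].copy(),
            target=self.target.copy(),
            strata=self.strata.copy(),
            missing_mask=self.missing_mask[cols].copy(),
            codebook={c: v for c, v in self.codebook.items() if c in cols},
            groups=self.groups,
        )

    def with_X(self, X: pd.DataFrame) -> "FeatureMatrix":
        return FeatureMatrix(
            X=X,
            target=self.target.copy(),
            strata=self.strata.copy(),
            missing_mask=self.missing_mask.copy(),
            codebook=dict(self.codebook),
            groups=self.groups,
        )

    def decode(self, column: str) -> pd.Series:
        """Decode an integer-coded categorical column back to its labels."""
        categories = self.codebook[column]
        return self.X[column].map(
            lambda c: categories[int(c)] if np.isfinite(c) else np.nan
        )


def observations_to_frame(observations: Sequence[TrialObservation]) -> pd.DataFrame:
    """Flatten observations to the delimited-text layout (one row per plot)."""
    rows = []
    for obs in observations:
        row: dict[str, object] = {
            "trial_id": obs.trial_id,
            "year": obs.year,
            "municipality": obs.municipality,
            "cultivar": obs.cultivar,
            "establishment": obs.establishment,
            "tillage": obs.tillage,
            "previous_crop": obs.previous_crop,
            "n_dose": obs.n_dose,
            "p_dose": obs.p_dose,
            "k_dose": obs.k_dose,
            "n_split_count": obs.n_split_count,
            "split_schedule": "|".join(f"{f:g}" for f in obs.split_schedule),
        }
        row.update({c: obs.soil.get(c.removeprefix("soil_"), obs.soil.get(c, np.nan))
                    for c in SOIL_COLUMNS})
        tissue = obs.tissue_dict()
        row.update({f"tissue_{p}": tissue[p] for p in NUTRIENTS})
        row.update({c: obs.climate.get(c, np.nan) for c in CLIMATE_COLUMNS})
        row[TARGET_COLUMN] = obs.yield_kg_ha
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_observations(frame: pd.DataFrame) -> list[TrialObservation]:
    """Inverse of :func:`observations_to_frame`."""
    observations = []
    for _, row in frame.iterrows():
        schedule = tuple(
            float(f) for f in str(row.get("split_schedule", "")).split("|") if f not in ("", "nan")
        )
        observations.append(
            TrialObservation(
                trial_id=str(row["trial_id"]),
                year=int(row["year"]),
                municipality=str(row["municipality"]),
                cultivar=str(row["cultivar"]),
                establishment=str(row["establishment"]),
                tillage=str(row["tillage"]),
                previous_crop=str(row["previous_crop"]),
                n_dose=float(row["n_dose"]),
                p_dose=float(row["p_dose"]),
                k_dose=float(row["k_dose"]),
                split_schedule=schedule,
                soil={c.removeprefix("soil_"): row[c] for c in SOIL_COLUMNS if c in row},
                tissue={p: row.get(f"tissue_{p}", np.nan) for p in NUTRIENTS},
                climate={c: row[c] for c in CLIMATE_COLUMNS if c in row},
                yield_kg_ha=float(row[TARGET_COLUMN]),
            )
        )
    return observations


def assemble(
    observations: Sequence[TrialObservation],
    groups: Iterable[str] | None = None,
    exclude: Sequence[str] = (),
    min_stratum_size: int = 4,
) -> FeatureMatrix:
    """Build the encoded feature matrix for the selected feature groups.

    Parameters
    ----------
    groups : iterable of {"climate", "management", "soil", "tissue", "fertilization"}
        Feature groups to include (default: all five).
    exclude : sequence of str
        Individual columns to drop after group selection (e.g. ``("p_dose",
        "k_dose")`` for the excluding-PK-fertilization configuration).
    min_stratum_size : int
        Strata (cultivar x establishment x municipality) smaller than this
        are collapsed into one pooled stratum.
    """
    if not observations:
        raise ValueError("no observations")
    selected = tuple(FEATURE_GROUPS) if groups is None else tuple(groups)
    unknown = [g for g in selected if g not in FEATURE_GROUPS]
    if unknown:
        raise ValueError(f"unknown feature groups: {unknown}; have {list(FEATURE_GROUPS)}")

    frame = observations_to_frame(observations)
    columns: list[str] = []
    for group in FEATURE_GROUPS:  # fixed order regardless of request order
        if group in selected:
            columns.extend(FEATURE_GROUPS[group])
    columns = [c for c in columns if c not in set(exclude)]

    codebook: dict[str, list[str]] = {}
    X = pd.DataFrame(index=frame.index)
    for col in columns:
        if col in CATEGORICAL_COLUMNS:
            categories = sorted(frame[col].dropna().astype(str).unique())
            codebook[col] = categories
            lookup = {c: i for i, c in enumerate(categories)}
            X[col] = frame[col].map(lambda v: lookup.get(str(v), np.nan)).astype(float)
        else:
            X[col] = pd.to_numeric(frame[col], errors="coerce").astype(float)

    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing columns: {all_missing}", UserWarning, stacklevel=2)
        X = X.drop(columns=all_missing)
        codebook = {c: v for c, v in codebook.items() if c in X.columns}

    strata = (
        frame["cultivar"].astype(str)
        + "/" + frame["establishment"].astype(str)
        + "/" + frame["municipality"].astype(str)
    )
    counts = strata.value_counts()
    small = counts[counts < min_stratum_size].index
    strata = strata.where(~strata.isin(small), POOLED_STRATUM)

    return FeatureMatrix(
        X=X,
        target=pd.to_numeric(frame[TARGET_COLUMN], errors="coerce").astype(float),
        strata=strata,
        missing_mask=X.isna(),
        codebook=codebook,
        groups=selected,
    )


def impute(matrix: FeatureMatrix, seed: int, max_rounds: int = 10) -> FeatureMatrix:
    """Fill missing cells by iterative random-forest imputation.

    Each incomplete column is regressed on all others with a small random
    forest, cycling until convergence or ``max_rounds`` rounds.  Observed
    cells are never altered; integer-coded categorical columns are rounded
    back to valid codes.
    """
    if not matrix.has_missing():
        return matrix.with_X(matrix.X.copy())
    all_missing = [c for c in matrix.X.columns if matrix.X[c].isna().all()]
    if all_missing:
        raise ValueError(f"cannot impute entirely missing columns: {all_missing}")
    frac = float(matrix.X.isna().to_numpy().mean())
    if frac >= 0.5:
        raise ValueError(f"missing fraction {frac:.2f} >= 0.5; refusing to impute")

    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=10, random_state=int(seed) % (2**31)),
        max_iter=max_rounds,
        tol=1e-3,
        random_state=int(seed) % (2**31),
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = pd.DataFrame(
        imputer.fit_transform(matrix.X),
        columns=matrix.X.columns,
        index=matrix.X.index,
    )
    # observed cells must pass through untouched
    filled = filled.where(matrix.X.isna(), matrix.X)
    for col, categories in matrix.codebook.items():
        filled[col] = filled[col].round().clip(0, len(categories) - 1)
    return matrix.with_X(filled)


def stratified_split(
    matrix: FeatureMatrix,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test partition (positional indices).

    Within each stratum rows are sampled without replacement at
    ``train_fraction`` (rounded half-up), then per-stratum counts are nudged
    by ±1 to hit the global train count within one row.  Singleton strata go
    to the training set with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = matrix.n_rows
    rng = np.random.default_rng(int(seed) % (2**31))
    strata = matrix.strata.reset_index(drop=True)
    labels = sorted(strata.unique())
    target_total = int(np.floor(n * train_fraction + 0.5))

    members = {lab: np.flatnonzero(strata.to_numpy() == lab) for lab in labels}
    counts: dict[str, int] = {}
    forced = set()
    for lab in labels:
        size = members[lab].size
        if size == 1:
            warnings.warn(
                f"singleton stratum {lab!r} assigned entirely to train", UserWarning, stacklevel=2
            )
            counts[lab] = 1
            forced.add(lab)
        else:
            c = int(np.floor(size * train_fraction + 0.5))
            counts[lab] = min(max(c, 1), size - 1)

    diff = target_total - sum(counts.values())
    remainders = {lab: members[lab].size * train_fraction - counts[lab] for lab in labels}
    while diff != 0:
        if diff > 0:
            adjustable = [
                lab for lab in labels
                if lab not in forced and counts[lab] < members[lab].size - 1
            ]
            if not adjustable:
                break
            lab = max(adjustable, key=lambda s: (remainders[s], s))
            counts[lab] += 1
            remainders[lab] -= 1
            diff -= 1
        else:
            adjustable = [lab for lab in labels if lab not in forced and counts[lab] > 1]
            if not adjustable:
                break
            lab = min(adjustable, key=lambda s: (remainders[s], s))
            counts[lab] -= 1
            remainders[lab] += 1
            diff += 1

    train_parts, test_parts = [], []
    for lab in labels:
        idx = members[lab]
        perm = idx[rng.permutation(idx.size)]
        train_parts.append(perm[: counts[lab]])
        test_parts.append(perm[counts[lab]:])
    train = np.sort(np.concatenate(train_parts)).astype(int)
    test = np.sort(np.concatenate(test_parts)).astype(int)
    return train, test


def tissue_to_clr(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace raw tissue concentration columns with their clr values.

    Requires complete, positive tissue columns; adds ``clr_Fv`` for the
    filling value so the clr block carries the full D-part geometry.
    """
    from .compositions import PARTS, close_composition, clr_transform

    present = [c for c in TISSUE_COLUMNS if c in matrix.X.columns]
    if len(present) != len(TISSUE_COLUMNS):
        raise ValueError("clr features need the full tissue column block")
    block = matrix.X[present]
    if block.isna().any().any() or (block <= 0).any().any():
        raise ValueError("clr features need complete, strictly positive tissue tests")
    clr_values = np.vstack(
        [
            clr_transform(
                close_composition(dict(zip(NUTRIENTS, row)))
            ).values
            for row in block.to_numpy()
        ]
    )
    X = matrix.X.drop(columns=present).copy()
    for i, part in enumerate(PARTS):
        X[f"clr_{part}"] = clr_values[:, i]
    return FeatureMatrix(
        X=X,
        target=matrix.target.copy(),
        strata=matrix.strata.copy(),
        missing_mask=X.isna(),
        codebook={c: v for c, v in matrix.codebook.items() if c in X.columns},
        groups=matrix.groups,
    )


def write_matrix(matrix: FeatureMatrix, path, codebook_path=None) -> None:
    """Write the encoded matrix (with target and strata) as delimited text."""
    out = matrix.X.copy()
    out[TARGET_COLUMN] = matrix.target
    out["_stratum"] = matrix.strata.to_numpy()
    out.to_csv(path, index=False)
    if codebook_path is not None:
        rows = [
            {"column": col, "code": i, "label": lab}
            for col, cats in matrix.codebook.items()
            for i, lab in enumerate(cats)
        ]
        pd.DataFrame(rows).to_csv(codebook_path, index=False)
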