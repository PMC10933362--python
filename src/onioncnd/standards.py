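"""Cultivar tissue nutrient standards and specimen diagnosis.

End stage of the pipeline: true-negative specimens (high-yielding, classified
nutritionally balanced) define, per cultivar, (i) clr nutrient standards —
per-part clr means, SDs and Student-t confidence intervals with the
back-transformed centroid concentrations — and (ii) lower/upper quartiles of
the raw concentrations.  New specimens are diagnosed against a standard by
standardized nutrient indices (excess / balanced / shortage per part) and by
their compositionally nearest balanced neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compositions import (
    DEFAULT_KAPPA,
    NUTRIENTS,
    ClrVector,
    Composition,
    NutrientStandard,
    clr_transform,
    fit_standard,
    nearest_balanced_neighbors,
    nutrient_indices,
    standards_to_frame,
)

#: (row, cultivar, tissue composition) triples, as produced by
#: :func:`onioncnd.yield_models.select_true_negatives`.
TnSpecimens = Sequence[tuple[int, str, Composition]]


class EmptyStandardsError(ValueError):
    """No cultivar reached the minimum specimen count."""


@dataclass
class StandardsTable:
    """Per-cultivar nutrient standards with derivation provenance."""

    standards: dict[str, NutrientStandard]
    provenance: dict[str, object] = field(default_factory=dict)

    def cultivars(self) -> list[str]:
        return sorted(self.standards)

    def __getitem__(self, cultivar: str) -> NutrientStandard:
        try:
            return self.standards[cultivar]
        except KeyError:
            raise KeyError(
                f"no standard for cultivar {cultivar!r}; available: {self.cultivars()}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return standards_to_frame(self.standards[c] for c in self.cultivars())

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Diagnosis:
    """Nutrient balance diagnosis of one specimen against its cultivar standard."""

    specimen_id: object
    cultivar: str
    indices: dict[str, float]
    verdicts: dict[str, str]            # part -> "shortage" | "balanced" | "excess"
    neighbors: list[tuple[int, float]]  # (reference-bank index, clr distance)
    index_threshold: float

    def to_frame(self) -> pd.DataFrame:
        parts = list(self.indices)
        return pd.DataFrame(
            {
                "part": parts,
                "index": [self.indices[p] for p in parts],
                "verdict": [self.verdicts[p] for p in parts],
            }
        )


def derive_standards(
    tn_specimens: TnSpecimens,
    alpha: float = 0.01,
    kappa: float = DEFAULT_KAPPA,
    min_specimens: int = 2,
    provenance: Mapping[str, object] | None = None,
) -> StandardsTable:
    """Fit clr nutrient standards per cultivar from true-negative specimens.

    Cultivars with fewer than ``min_specimens`` records are skipped with a
    warning; an empty result raises :class:`EmptyStandardsError`.
    """
    by_cultivar: dict[str, list[ClrVector]] = {}
    for _, cultivar, comp in tn_specimens:
        by_cultivar.setdefault(cultivar, []).append(clr_transform(comp))
    standards: dict[str, NutrientStandard] = {}
    counts: dict[str, int] = {}
    for cultivar in sorted(by_cultivar):
        specimens = by_cultivar[cultivar]
        if len(specimens) < min_specimens:
            warnings.warn(
                f"cultivar {cultivar!r} has {len(specimens)} TN specimens "
                f"(< {min_specimens}); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        standards[cultivar] = fit_standard(specimens, cultivar, alpha=alpha, kappa=kappa)
        counts[cultivar] = len(specimens)
    if not standards:
        raise EmptyStandardsError("no cultivar qualifies for standards derivation")
    meta = dict(provenance or {})
    meta["tn_counts"] = counts
    meta["alpha"] = alpha
    return StandardsTable(standards=standards, provenance=meta)


def concentration_quartiles(
    tn_specimens: TnSpecimens,
    min_specimens: int = 4,
) -> pd.DataFrame:
    """Lower/upper quartiles (25th/75th, linear interpolation) of raw
    concentrations per cultivar x nutrient among true-negative specimens.

    Returns a long table: cultivar, part, lq_g_kg, hq_g_kg, n.
    """
    by_cultivar: dict[str, list[Composition]] = {}
    for _, cultivar, comp in tn_specimens:
        by_cultivar.setdefault(cultivar, []).append(comp)
    rows = []
    for cultivar in sorted(by_cultivar):
        comps = by_cultivar[cultivar]
        if len(comps) < min_specimens:
            warnings.warn(
                f"cultivar {cultivar!r} has {len(comps)} TN specimens "
                f"(< {min_specimens}); skipped in quartiles",
                UserWarning,
                stacklevel=2,
            )
            continue
        stack = np.vstack([c.concentrations for c in comps])
        lq = np.percentile(stack, 25, axis=0, method="linear")
        hq = np.percentile(stack, 75, axis=0, method="linear")
        rows.extend(
            {"cultivar": cultivar, "part": part, "lq_g_kg": lo, "hq_g_kg": hi, "n": len(comps)}
            for part, lo, hi in zip(NUTRIENTS, lq, hq)
        )
    return pd.DataFrame(rows, columns=["cultivar", "part", "lq_g_kg", "hq_g_kg", "n"])


def diagnose(
    specimen: Composition,
    standards: StandardsTable,
    cultivar: str,
    reference_bank: Sequence[ClrVector] = (),
    k: int = 5,
    index_threshold: float = 1.0,
    specimen_id: object = None,
) -> Diagnosis:
    """Diagnose one specimen against its cultivar standard.

    Per part: index ``I = (clr - clr*) / SD*``; verdict *excess* if
    ``I > index_threshold``, *shortage* if ``I < -index_threshold``, else
    *balanced*.  When a reference bank of balanced clr vectors is supplied,
    the k compositionally nearest are reported as diagnostic context.
    """
    std = standards[cultivar]
    clr = clr_transform(specimen)
    indices = nutrient_indices(clr, std)
    verdicts = {
        part: ("excess" if value > index_threshold
               else "shortage" if value < -index_threshold
               else "balanced")
        for part, value in indices.items()
    }
    neighbors = (
        nearest_balanced_neighbors(clr, reference_bank, k=k) if len(reference_bank) else []
    )
    return Diagnosis(
        specimen_id=specimen_id,
        cultivar=cultivar,
        indices=indices,
        verdicts=verdicts,
        neighbors=neighbors,
        index_threshold=index_threshold,
    )


def standards_from_frame(frame: pd.DataFrame, kappa: float = DEFAULT_KAPPA) -> StandardsTable:
    """Rebuild a StandardsTable from its delimited-text long form."""
    from .compositions import clr_back_transform

    standards: dict[str, NutrientStandard] = {}
    for cultivar, block in frame.groupby("cultivar"):
        block = block.set_index("part").loc[list(block["part"])]  # keep file order
        labels = tuple(block.index)
        mean = block["clr_mean"].to_numpy(dtype=float)
        standards[str(cultivar)] = NutrientStandard(
            cultivar=str(cultivar),
            labels=labels,
            clr_mean=mean,
            clr_sd=block["clr_sd"].to_numpy(dtype=float),
            ci_low=block["ci_low"].to_numpy(dtype=float),
            ci_high=block["ci_high"].to_numpy(dtype=float),
            alpha=float(block["alpha"].iloc[0]),
            n=int(block["n"].iloc[0]),
            centroid=clr_back_transform(ClrVector(labels, mean), kappa=kappa),
        )
    return StandardsTable(standards=standards)


def read_standards(path, kappa: float = DEFAULT_KAPPA) -> StandardsTable:
    return standards_from_frame(pd.read_csv(path), kappa=kappa)


def plot_indices(diagnosis: Diagnosis, path, title: str | None = None) -> None:
    """Histogram-style bar chart of nutrient indices (excess up, shortage down)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    parts = list(diagnosis.indices)
    values = [diagnosis.indices[p] for p in parts]
    colors = ["#b2413e" if abs(v) > diagnosis.index_threshold else "#41658a" for v in values]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(parts, values, color=colors)
    ax.axhline(0, color="black", lw=0.8)
    for level in (diagnosis.index_threshold, -diagnosis.index_threshold):
        ax.axhline(level, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("nutrient index (SD units)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
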