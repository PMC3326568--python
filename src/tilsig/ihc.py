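"""Immunohistochemistry core scoring.

Converts per-core intraepithelial lymphocyte counts into densities
normalized by the epithelial fraction of the scoring grid (area 0.56 mm²
under a ×20 objective), selects one representative core per sample, and
correlates markers across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKERS",
    "IHCCoreMeasurement",
    "TILDensity",
    "normalize_density",
    "select_core",
    "selected_densities",
    "marker_correlation",
    "read_ihc_csv",
    "write_density_tsv",
]

MARKERS = ("CD3", "CD8", "CD4", "CD20", "TIA1")

#: Grid area in mm² of the scoring eyepiece grid at ×20 magnification.
DEFAULT_GRID_AREA_MM2 = 0.56


@dataclass(frozen=True)
class IHCCoreMeasurement:
    """One stained tissue core: marker-positive intraepithelial count and
    the fraction of the grid occupied by tumor epithelium."""

    sample_id: str
    core_id: str
    marker: str
    raw_count: int
    epithelial_fraction: float
    grid_area_mm2: float = DEFAULT_GRID_AREA_MM2

    def __post_init__(self) -> None:
        if self.raw_count < 0:
            raise ValueError("raw_count must be non-negative")
        if not 0 < self.epithelial_fraction <= 1:
            raise ValueError(
                "epithelial_fraction must be in (0, 1]; zero-epithelium "
                "cores are uninterpretable"
            )
        if not self.grid_area_mm2 > 0:
            raise ValueError("grid_area_mm2 must be positive")


@dataclass(frozen=True)
class TILDensity:
    """Epithelium-normalized lymphocyte density for one sample/marker."""

    sample_id: str
    marker: str
    normalized_count: float
    per_mm2: float


def normalize_density(core: IHCCoreMeasurement) -> TILDensity:
    """Density = raw count ÷ epithelial fraction (and per mm² of grid)."""
    normalized = core.raw_count / core.epithelial_fraction
    return TILDensity(
        sample_id=core.sample_id,
        marker=core.marker,
        normalized_count=normalized,
        per_mm2=normalized / core.grid_area_mm2,
    )


def select_core(cores: list[IHCCoreMeasurement]) -> IHCCoreMeasurement:
    """Pick the representative core for one sample/marker.

    The scoring protocol's two criteria (tumor/stroma ratio closest to
    50:50, then highest density) are applied lexicographically, with
    core_id as the final deterministic tie-break.
    """
    if not cores:
        raise ValueError("no cores to select from")
    return min(
        cores,
        key=lambda c: (
            abs(c.epithelial_fraction - 0.5),
            -normalize_density(c).normalized_count,
            c.core_id,
        ),
    )


def selected_densities(
    cores: list[IHCCoreMeasurement], marker: str | None = None
) -> pd.DataFrame:
    """Per-sample density after core selection; optionally restricted to
    one marker.  Returns columns sample_id, marker, normalized_count, per_mm2."""
    grouped: dict[tuple[str, str], list[IHCCoreMeasurement]] = {}
    for core in cores:
        if marker is not None and core.marker != marker:
            continue
        grouped.setdefault((core.sample_id, core.marker), []).append(core)
    rows = []
    for (sample, mk), group in sorted(grouped.items()):
        density = normalize_density(select_core(group))
        rows.append(
            {
                "sample_id": sample,
                "marker": mk,
                "normalized_count": density.normalized_count,
                "per_mm2": density.per_mm2,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "marker", "normalized_count", "per_mm2"])


def _exact_spearman_p(xv: np.ndarray, yv: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (small n).

    Enumerates all pairings of the x-ranks against the y-ranks in
    vectorized chunks; handles ties via average ranks and Pearson of ranks.
    """
    from itertools import islice, permutations

    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    observed = float(rxc @ ryc / denom)
    count = 0
    total = 0
    perm_iter = permutations(rxc)
    while True:
        chunk = np.array(list(islice(perm_iter, 200_000)))
        if chunk.size == 0:
            break
        rhos = chunk @ ryc / denom
        count += int((np.abs(rhos) >= abs(observed) - 1e-12).sum())
        total += len(rhos)
    return count / total


def marker_correlation(
    x: dict[str, float] | pd.Series, y: dict[str, float] | pd.Series
) -> tuple[float, float]:
    """Spearman correlation between two markers' densities paired by sample.

    Uses the exact permutation distribution for ≤ 10 pairs and the
    t-approximation otherwise.  Returns (rho, two-sided p).
    """
    xs = pd.Series(dict(x) if not isinstance(x, pd.Series) else x)
    ys = pd.Series(dict(y) if not isinstance(y, pd.Series) else y)
    common = xs.index.intersection(ys.index)
    if len(common) < 3:
        raise ValueError("need at least 3 complete sample pairs")
    xv = xs.loc[common].to_numpy(dtype=float)
    yv = ys.loc[common].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant marker vector; correlation undefined")
    rho = float(stats.spearmanr(xv, yv).statistic)
    if len(common) <= 10:
        return rho, _exact_spearman_p(xv, yv)
    return rho, float(stats.spearmanr(xv, yv).pvalue)


def read_ihc_csv(path: str | Path) -> list[IHCCoreMeasurement]:
    """Read cores from CSV: sample_id, core_id, marker, raw_count,
    epithelial_fraction[, grid_area_mm2]."""
    frame = pd.read_csv(path, dtype={"sample_id": str, "core_id": str, "marker": str})
    cores = []
    for row in frame.itertuples(index=False):
        kwargs = dict(
            sample_id=row.sample_id,
            core_id=row.core_id,
            marker=row.marker,
            raw_count=int(row.raw_count),
            epithelial_fraction=float(row.epithelial_fraction),
        )
        if hasattr(row, "grid_area_mm2") and not pd.isna(row.grid_area_mm2):
            kwargs["grid_area_mm2"] = float(row.grid_area_mm2)
        cores.append(IHCCoreMeasurement(**kwargs))
    return cores


def write_ihc_csv(cores: list[IHCCoreMeasurement], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "core_id": c.core_id,
                "marker": c.marker,
                "raw_count": c.raw_count,
                "epithelial_fraction": c.epithelial_fraction,
                "grid_area_mm2": c.grid_area_mm2,
            }
            for c in cores
        ]
    )
    frame.to_csv(path, index=False)


def write_density_tsv(densities: pd.DataFrame, path: str | Path) -> None:
    densities.to_csv(path, sep="\t", index=False)
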