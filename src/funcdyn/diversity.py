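"""Functional dispersion (FDis) of seasonal assemblages.

FDis is the weighted mean distance of species to the weighted centroid of
the assemblage in functional-trait space:

    c = sum_j w_j x_j / sum_j w_j
    FDis = sum_j w_j ||x_j - c|| / sum_j w_j

computed here in a principal-coordinates embedding of the functional
dissimilarity matrix G. Three weightings are reported per assemblage:

- FDo: occurrence (presence/absence) -- a functional-richness estimate;
- FDn: relative number of individuals captured;
- FDw: relative biomass (count x mean individual mass).

FDn and FDw equal FDo when abundance is evenly spread over the present
species and fall below it as functional evenness declines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from funcdyn.traits import FunctionalDissimilarity, _pcoa_eig

__all__ = [
    "AssemblageSeries",
    "FDisEstimate",
    "embed_species",
    "fdis",
    "fd_series",
]

SEASONS = ("dry", "wet")
#: chronological order of seasons within a calendar year: the dry season
#: (Nov-May, labelled by the year of its Jan-May span) precedes the wet
#: season (Jun-Oct) of the same year.
SEASON_ORDER = {"dry": 0, "wet": 1}


@dataclass
class AssemblageSeries:
    """Seasonal capture counts per (year, season, habitat).

    ``counts`` is a long-format DataFrame with columns
    ``year, season, habitat, species, count`` (non-negative integers).
    ``mean_biomass_g`` maps species to mean individual mass in grams and is
    required for biomass-weighted FDis.
    """

    counts: pd.DataFrame
    mean_biomass_g: pd.Series | None = None

    REQUIRED = ("year", "season", "habitat", "species", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.counts.columns]
        if missing:
            raise ValueError(f"counts frame missing columns: {missing}")
        if (self.counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.counts["season"]) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        key = ["year", "season", "habitat", "species"]
        if self.counts.duplicated(key).any():
            dupes = self.counts[self.counts.duplicated(key, keep=False)]
            raise ValueError(
                f"duplicate (year, season, habitat, species) rows:\n{dupes.head()}"
            )

    @property
    def species(self) -> list[str]:
        return sorted(self.counts["species"].unique())

    @property
    def habitats(self) -> list[str]:
        return sorted(self.counts["habitat"].unique())

    def keys(self) -> list[tuple[int, str, str]]:
        """All (year, season, habitat) record keys in chronological order."""
        uniq = self.counts[["year", "season", "habitat"]].drop_duplicates()
        return sorted(
            map(tuple, uniq.itertuples(index=False)),
            key=lambda k: (k[0], SEASON_ORDER[k[1]], k[2]),
        )

    def record(self, year: int, season: str, habitat: str) -> pd.Series:
        """Counts per species for one assemblage (positive entries only)."""
        mask = (
            (self.counts["year"] == year)
            & (self.counts["season"] == season)
            & (self.counts["habitat"] == habitat)
        )
        sub = self.counts[mask]
        series = sub.set_index("species")["count"].astype(float)
        return series[series > 0]

    def iter_records(self) -> Iterator[tuple[tuple[int, str, str], pd.Series]]:
        for key in self.keys():
            yield key, self.record(*key)


@dataclass
class FDisEstimate:
    """FDis of one assemblage under the three weightings."""

    year: int
    season: str
    habitat: str
    S: int
    FDo: float
    FDn: float
    FDw: float
    total_captures: float


def embed_species(
    fd: FunctionalDissimilarity, tol: float = 1e-10
) -> pd.DataFrame:
    """PCoA embedding of G, retaining all positive-eigenvalue axes.

    If G is non-Euclidean (the double-centered matrix has negative
    eigenvalues beyond ``tol``), the square-root correction is applied:
    distances are replaced by their square roots, which for the bounded
    dissimilarities produced by the weighted Gower combination yields a
    representable matrix. Residual negative eigenvalues after correction
    are dropped.
    """
    if fd.n_species < 2:
        raise ValueError("embedding needs at least 2 species")
    g = fd.values()
    eigval, _ = _pcoa_eig(g)
    scale = max(abs(eigval[0]), 1.0)
    if eigval[-1] < -tol * scale:
        g = np.sqrt(g)
        eigval, eigvec = _pcoa_eig(g)
    else:
        eigval, eigvec = _pcoa_eig(g)
    pos = eigval > max(tol, tol * scale)
    if not pos.any():
        raise ValueError("G has no positive eigenvalue; species are identical")
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return pd.DataFrame(
        coords,
        index=fd.species_ids,
        columns=[f"axis{i + 1}" for i in range(int(pos.sum()))],
    )


def fdis(coords: pd.DataFrame | np.ndarray, weights: np.ndarray | pd.Series) -> float:
    """Weighted distance-to-centroid dispersion of a species set.

    Species with zero weight do not contribute; all-zero weights are an
    error. The result is invariant to rescaling the weights and to rigid
    motions of the coordinates.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError("weights and coordinates disagree in length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    w = w / total
    centroid = w @ x
    dist = np.linalg.norm(x - centroid, axis=1)
    return float(w @ dist)


def fd_series(
    assemblages: AssemblageSeries,
    fd: FunctionalDissimilarity,
    coords: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """FDis per (year, season, habitat) under all three weightings.

    Returns a tidy frame ``year, season, habitat, S, total_captures, FDo,
    FDn, FDw``. Single-species assemblages score 0 on all indices; empty
    records yield NaN (no assemblage exists). Biomass weights are
    count x mean individual mass, so ``mean_biomass_g`` must cover every
    captured species.
    """
    unknown = set(assemblages.counts["species"]) - set(fd.species_ids)
    if unknown:
        raise KeyError(f"species absent from the functional pool: {sorted(unknown)}")
    if coords is None:
        coords = embed_species(fd)
    biomass = assemblages.mean_biomass_g

    rows = []
    for (year, season, habitat), counts in assemblages.iter_records():
        s = int((counts > 0).sum())
        total = float(counts.sum())
        if s == 0:
            rows.append((year, season, habitat, 0, 0.0, np.nan, np.nan, np.nan))
            continue
        present = list(counts.index)
        x = coords.loc[present].to_numpy()
        occ = np.ones(s)
        fdo = fdis(x, occ)
        fdn = fdis(x, counts.to_numpy())
        if biomass is not None:
            missing = set(present) - set(biomass.index)
            if missing:
                raise KeyError(f"no mean biomass for species: {sorted(missing)}")
            fdw = fdis(x, counts.to_numpy() * biomass.loc[present].to_numpy())
        else:
            fdw = np.nan
        rows.append((year, season, habitat, s, total, fdo, fdn, fdw))

    return pd.DataFrame(
        rows,
        columns=[
            "year",
            "season",
            "habitat",
            "S",
            "total_captures",
            "FDo",
            "FDn",
            "FDw",
        ],
    )
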