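"""Functional trait space construction.

Builds a species-by-species functional dissimilarity matrix **G** from a
table of mixed traits: several compositional (multivariate) trait
categories -- e.g. habitat use, vertical stratum, diet, temporal activity,
each a vector of proportions summing to one per species -- plus mean
individual biomass in grams.

The construction follows the weighted Gower scheme common in trait-based
community ecology:

1. biomass is log10-transformed and divided by its standard deviation;
2. each compositional category yields a Euclidean distance matrix, which is
   reduced by principal coordinates analysis (PCoA), retaining the leading
   axes that explain at least a target share ``sk`` of the variance;
3. per-category dissimilarities ``D_k`` (Euclidean in the retained axes;
   absolute difference for biomass) are combined as

       g_ij = sum_k W_k * D_ijk / sum_k W_k

   with ``W_k = 1`` for biomass and ``W_k = 1/sk`` for each reduced
   multivariate category, so every trait contributes comparably to
   functional differentiation regardless of its dimensionality.

The resulting **G** is summarised as an agglomerative dendrogram whose low
merge heights flag functionally redundant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TraitTable",
    "ReducedTraitBlock",
    "FunctionalDissimilarity",
    "Dendrogram",
    "validate_trait_table",
    "standardize_biomass",
    "block_distance",
    "pcoa_reduce",
    "gower_combine",
    "build_trait_space",
    "functional_dendrogram",
]

#: row sums further than this from 1 are a hard error
ROW_SUM_TOLERANCE = 1e-3


class TraitValidationError(ValueError):
    """Raised when a trait table violates its compositional contract."""


@dataclass
class TraitTable:
    """Species-by-trait table: compositional categories plus biomass.

    Parameters
    ----------
    species_ids
        Ordered species codes; no duplicates.
    categories
        Mapping of category name to a species x level DataFrame of
        proportions (each row sums to 1). Row index must equal
        ``species_ids``.
    biomass_g
        Mean individual biomass per species, grams, indexed by species.
    """

    species_ids: list[str]
    categories: dict[str, pd.DataFrame]
    biomass_g: pd.Series

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def category_matrix(self, name: str) -> pd.DataFrame:
        if name not in self.categories:
            raise KeyError(
                f"unknown trait category {name!r}; have {sorted(self.categories)}"
            )
        return self.categories[name]


@dataclass
class ReducedTraitBlock:
    """A trait category after PCoA reduction.

    ``sk`` is the share of total positive-eigenvalue variance explained by
    the retained axes (the Gower weight for this block is ``1/sk``).
    """

    category_name: str
    coords: pd.DataFrame  # species x retained axes
    sk: float
    n_axes: int

    def __post_init__(self) -> None:
        if not 0.0 < self.sk <= 1.0 + 1e-12:
            raise ValueError(f"sk must lie in (0, 1], got {self.sk}")
        if self.n_axes < 1:
            raise ValueError("at least one axis must be retained")


@dataclass
class FunctionalDissimilarity:
    """The combined functional dissimilarity matrix G with its ingredients."""

    species_ids: list[str]
    G: pd.DataFrame
    per_trait_D: dict[str, pd.DataFrame]
    weights: dict[str, float]

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def values(self) -> np.ndarray:
        return self.G.to_numpy()

    def subset(self, species: Sequence[str]) -> "FunctionalDissimilarity":
        """Restrict G to a subset of species (order preserved)."""
        species = list(species)
        missing = set(species) - set(self.species_ids)
        if missing:
            raise KeyError(f"species not in pool: {sorted(missing)}")
        return FunctionalDissimilarity(
            species_ids=species,
            G=self.G.loc[species, species],
            per_trait_D={k: d.loc[species, species] for k, d in self.per_trait_D.items()},
            weights=dict(self.weights),
        )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over species in g_ij units."""

    species_ids: list[str]
    linkage_matrix: np.ndarray
    method: str = "average"

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        labels = self.species_ids

        def _recurse(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{labels[node.id]}:{length:.6g}"
            left = _recurse(node.left, node.dist)
            right = _recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = _recurse(tree.left, tree.dist)
        right = _recurse(tree.right, tree.dist)
        return f"({left},{right});"


def validate_trait_table(table: TraitTable) -> TraitTable:
    """Validate and lightly repair a trait table.

    Compositional rows whose sum deviates from 1 by no more than
    ``ROW_SUM_TOLERANCE`` are renormalized in place; larger deviations and
    nonpositive biomass are hard errors naming the offending species.
    """
    if table.n_species < 2:
        raise TraitValidationError("trait table needs at least 2 species")
    if len(set(table.species_ids)) != table.n_species:
        dupes = [s for s in set(table.species_ids) if table.species_ids.count(s) > 1]
        raise TraitValidationError(f"duplicate species codes: {sorted(dupes)}")

    fixed: dict[str, pd.DataFrame] = {}
    for name, block in table.categories.items():
        if list(block.index) != list(table.species_ids):
            block = block.reindex(table.species_ids)
        arr = block.to_numpy(dtype=float)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-9):
            bad = block.index[np.any((arr < -1e-12) | (arr > 1 + 1e-9), axis=1)]
            raise TraitValidationError(
                f"category {name!r}: proportions outside [0, 1] for {list(bad)}"
            )
        sums = arr.sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_TOLERANCE
        if off.any():
            bad = [f"{sp} (sum={s:.4g})" for sp, s in zip(block.index[off], sums[off])]
            raise TraitValidationError(
                f"category {name!r}: compositional rows do not sum to 1: {bad}"
            )
        fixed[name] = pd.DataFrame(
            arr / sums[:, None], index=block.index, columns=block.columns
        )

    biomass = table.biomass_g.reindex(table.species_ids)
    if biomass.isna().any():
        raise TraitValidationError(
            f"missing biomass for {list(biomass.index[biomass.isna()])}"
        )
    if (biomass <= 0).any():
        raise TraitValidationError(
            f"nonpositive biomass for {list(biomass.index[biomass <= 0])}"
        )
    return TraitTable(list(table.species_ids), fixed, biomass.astype(float))


def standardize_biomass(biomass_g: pd.Series | np.ndarray) -> pd.Series:
    """log10-transform biomass and scale to unit standard deviation.

    Returns log10(mass) / sd(log10(mass)), using the sample standard
    deviation (ddof=1). The output has sd exactly 1.
    """
    values = pd.Series(biomass_g, dtype=float)
    if (values <= 0).any():
        raise ValueError("biomass must be strictly positive")
    logged = np.log10(values)
    sd = logged.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("biomass values are all identical; cannot standardize")
    return logged / sd


def block_distance(table: TraitTable, category: str) -> pd.DataFrame:
    """Pairwise Euclidean distances over one category's proportion rows."""
    block = table.category_matrix(category)
    dist = squareform(pdist(block.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(dist, index=block.index, columns=block.index)


def _double_center(dist: np.ndarray) -> np.ndarray:
    """Gower double-centering of -0.5 * D^2."""
    a = -0.5 * dist**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pcoa_eig(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the double-centered matrix, descending order."""
    b = _double_center(dist)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]  # stable within ties by earlier index
    return eigval[order], eigvec[:, order]


def pcoa_reduce(
    dist: pd.DataFrame, retention: float = 0.75, category_name: str = ""
) -> ReducedTraitBlock:
    """Classical PCoA, retaining leading axes covering >= `retention` variance.

    Only positive eigenvalues enter the variance denominator; axes are
    added in descending eigenvalue order until their cumulative share of
    positive-eigenvalue variance reaches the retention threshold. ``sk``
    records that cumulative share.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    eigval, eigvec = _pcoa_eig(d)
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]))
    if not pos.any():
        raise ValueError("no positive eigenvalue; degenerate distance matrix")
    total = eigval[pos].sum()
    cum = np.cumsum(np.where(pos, eigval, 0.0)) / total
    n_axes = int(np.searchsorted(cum, retention - 1e-12) + 1)
    n_axes = min(n_axes, int(pos.sum()))
    sk = float(cum[n_axes - 1])
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(d.shape[0])
    frame = pd.DataFrame(
        coords, index=index, columns=[f"axis{i + 1}" for i in range(n_axes)]
    )
    return ReducedTraitBlock(
        category_name=category_name or "block", coords=frame, sk=sk, n_axes=n_axes
    )


def gower_combine(
    blocks: Sequence[ReducedTraitBlock],
    biomass_std: pd.Series | None = None,
    normalize: bool = True,
) -> FunctionalDissimilarity:
    """Combine per-trait dissimilarities into the weighted Gower matrix G.

    ``D_k`` is Euclidean distance in block k's retained coordinates
    (absolute difference for standardized biomass). With ``normalize`` each
    ``D_k`` is divided by its maximum, bounding every trait's contribution
    to [0, 1]. Weights are ``1/sk`` for multivariate blocks and 1 for
    biomass; ``g_ij = sum_k W_k D_ijk / sum_k W_k``.
    """
    if not blocks and biomass_std is None:
        raise ValueError("need at least one trait block or biomass")
    species: list[str] | None = None
    for b in blocks:
        ids = list(b.coords.index)
        if species is None:
            species = ids
        elif ids != species:
            raise ValueError(
                f"species mismatch between blocks ({b.category_name!r})"
            )
    if biomass_std is not None:
        if species is None:
            species = list(biomass_std.index)
        elif list(biomass_std.index) != species:
            raise ValueError("biomass index does not match trait blocks")
    assert species is not None

    per_trait: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    for b in blocks:
        d = squareform(pdist(b.coords.to_numpy(), metric="euclidean"))
        per_trait[b.category_name] = d
        weights[b.category_name] = 1.0 / b.sk
    if biomass_std is not None:
        v = biomass_std.to_numpy(dtype=float)
        per_trait["biomass"] = np.abs(v[:, None] - v[None, :])
        weights["biomass"] = 1.0

    if normalize:
        for k, d in per_trait.items():
            m = d.max()
            if m > 0:
                per_trait[k] = d / m

    wsum = sum(weights.values())
    g = sum(weights[k] * per_trait[k] for k in per_trait) / wsum
    np.fill_diagonal(g, 0.0)
    g = (g + g.T) / 2.0

    return FunctionalDissimilarity(
        species_ids=species,
        G=pd.DataFrame(g, index=species, columns=species),
        per_trait_D={
            k: pd.DataFrame(d, index=species, columns=species)
            for k, d in per_trait.items()
        },
        weights=weights,
    )


def build_trait_space(
    table: TraitTable,
    retention: float = 0.75,
    normalize: bool = True,
) -> FunctionalDissimilarity:
    """Full trait-space pipeline: validate, reduce each category, combine.

    Convenience wrapper chaining :func:`validate_trait_table`,
    :func:`standardize_biomass`, per-category :func:`block_distance` +
    :func:`pcoa_reduce`, and :func:`gower_combine`.
    """
    table = validate_trait_table(table)
    blocks = [
        pcoa_reduce(block_distance(table, name), retention, category_name=name)
        for name in table.categories
    ]
    biomass_std = standardize_biomass(table.biomass_g)
    return gower_combine(blocks, biomass_std, normalize=normalize)


def functional_dendrogram(
    fd: FunctionalDissimilarity, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of G; merge heights in g_ij units."""
    if fd.n_species < 2:
        raise ValueError("dendrogram needs at least 2 species")
    condensed = squareform(fd.values(), checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(species_ids=list(fd.species_ids), linkage_matrix=z, method=linkage)
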