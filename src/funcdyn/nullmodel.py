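"""Random-extinction null model for the richness-FDis association (SFD).

The null expectation of functional dispersion at each richness level is
built by simulating random extinction trajectories from the full species
pool: species are removed one at a time, uniformly at random, until a
single species remains, and the occurrence-weighted FDis of every
intermediate assemblage is recorded. Because each trajectory is a uniform
random permutation, every r-species subset of the pool is equally likely
at richness level r, so the per-level sample distribution converges to the
exhaustive enumeration over subsets.

Observed FDis values are contrasted against the null mean at the same
richness: negative deviations indicate environmental filtering (a narrower
trait subset than random assembly predicts), positive deviations indicate
limiting similarity. The null mean is an expectation for occurrence-based
FDis, and for the count- and biomass-weighted variants only when evenness
is maximal, so their deviations fold in a functional-evenness component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from funcdyn.diversity import embed_species, fdis
from funcdyn.traits import FunctionalDissimilarity

__all__ = [
    "NullCurve",
    "DeviationRecord",
    "simulate_extinction_trajectories",
    "null_expectation",
    "deviations",
    "sfd_shape_summary",
]


@dataclass
class NullCurve:
    """Per-richness distribution of null FDis values (the SFD)."""

    pool_species: list[str]
    n_traj: int
    samples: dict[int, np.ndarray]  # richness r -> n_traj FDis values
    pool_fdis: float
    seed: int | None = None

    @property
    def pool_size(self) -> int:
        return len(self.pool_species)

    def mean(self, r: int) -> float:
        if r == self.pool_size:
            return self.pool_fdis
        return float(self.samples[r].mean())

    def quantiles(self, r: int, q: tuple[float, float] = (0.025, 0.975)) -> tuple[float, float]:
        if r == self.pool_size:
            return (self.pool_fdis, self.pool_fdis)
        lo, hi = np.quantile(self.samples[r], q)
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        """Tidy summary: r, mean, q025, q975 for r = 1 .. pool size."""
        rows = []
        for r in range(1, self.pool_size + 1):
            lo, hi = self.quantiles(r)
            rows.append((r, self.mean(r), lo, hi))
        return pd.DataFrame(rows, columns=["r", "mean", "q025", "q975"])


@dataclass
class DeviationRecord:
    """Signed departure of observed FDis from the null mean at richness S."""

    year: int
    season: str
    habitat: str
    S: int
    dFDo: float
    dFDn: float
    dFDw: float


def simulate_extinction_trajectories(
    fd: FunctionalDissimilarity,
    n_traj: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullCurve:
    """Simulate random extinction trajectories and collect the null SFD.

    Each trajectory is a uniform random removal order over the pool,
    yielding one nested assemblage per richness level r = pool-1 .. 1
    whose occurrence-based FDis is recorded (a single remaining species has
    zero functional diversity by definition). Identical subsets are
    memoised, which keeps the 1,000-trajectory default fast for pools of a
    dozen species.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    s = fd.n_species
    if s < 2:
        raise ValueError("pool must contain at least 2 species")
    if rng is None:
        rng = np.random.default_rng(seed)

    coords = embed_species(fd).to_numpy()
    cache: dict[frozenset[int], float] = {}

    def subset_fdis(idx: np.ndarray) -> float:
        if idx.size == 1:
            return 0.0
        key = frozenset(idx.tolist())
        val = cache.get(key)
        if val is None:
            val = fdis(coords[idx], np.ones(idx.size))
            cache[key] = val
        return val

    samples = {r: np.empty(n_traj) for r in range(1, s)}
    for t in range(n_traj):
        order = rng.permutation(s)
        for r in range(s - 1, 0, -1):
            samples[r][t] = subset_fdis(order[:r])

    pool_fdis = fdis(coords, np.ones(s))
    return NullCurve(
        pool_species=list(fd.species_ids),
        n_traj=n_traj,
        samples=samples,
        pool_fdis=pool_fdis,
        seed=seed,
    )


def null_expectation(curve: NullCurve, S: int) -> tuple[float, tuple[float, float]]:
    """Null mean and 95% interval of FDis at richness S.

    At S equal to the pool size there is a single possible assemblage, so
    the expectation is the pool FDis with a zero-width interval; S = 1 is
    exactly zero.
    """
    if not 1 <= S <= curve.pool_size:
        raise ValueError(
            f"richness {S} outside the pool range 1..{curve.pool_size}"
        )
    return curve.mean(S), curve.quantiles(S)


def deviations(observed: pd.DataFrame, curve: NullCurve) -> pd.DataFrame:
    """Deviations dFDo/dFDn/dFDw of observed FDis from the null mean.

    ``observed`` is the tidy output of :func:`funcdyn.diversity.fd_series`.
    The same occurrence-based null mean is subtracted from all three
    indices (it is the expectation for FDn/FDw only at maximal evenness,
    so those deviations also reflect functional evenness). Records with
    S = 0 or S above the pool size are returned as missing.
    """
    rows = []
    for rec in observed.itertuples(index=False):
        if rec.S < 1 or rec.S > curve.pool_size:
            rows.append((rec.year, rec.season, rec.habitat, rec.S, np.nan, np.nan, np.nan))
            continue
        mean_s = curve.mean(int(rec.S))
        rows.append(
            (
                rec.year,
                rec.season,
                rec.habitat,
                rec.S,
                rec.FDo - mean_s,
                rec.FDn - mean_s,
                rec.FDw - mean_s,
            )
        )
    return pd.DataFrame(
        rows, columns=["year", "season", "habitat", "S", "dFDo", "dFDn", "dFDw"]
    )


def sfd_shape_summary(curve: NullCurve) -> dict:
    """Saturation of the null SFD curve.

    Reports the marginal FDis gain per added species,
    ``mean_{r+1} - mean_r``, and a saturation index: the mean gain over the
    last half of the richness range divided by the mean gain over the first
    half. A linear SFD (functional complementarity, sensitivity to species
    loss) gives a ratio near 1; an asymptotic SFD (intrinsic functional
    redundancy, resilience to random loss) gives a ratio near 0.
    """
    s = curve.pool_size
    if s < 3:
        raise ValueError("shape summary needs a pool of at least 3 species")
    means = np.array([curve.mean(r) for r in range(1, s + 1)])
    gains = np.diff(means)  # gain at r -> r+1, for r = 1 .. s-1
    half = len(gains) // 2
    first = gains[:half].mean()
    last = gains[-half:].mean()
    ratio = float("inf") if first == 0 else max(float(last / first), 0.0)
    return {
        "marginal_gains": pd.Series(gains, index=range(1, s), name="gain"),
        "saturation_index": ratio,
    }
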