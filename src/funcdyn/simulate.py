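"""Synthetic study-system generator.

Emulates a two-habitat, two-season, multi-decadal small-mammal monitoring
dataset with the statistical structure the analysis modules assume:

- a pool of 13 species with compositional traits (habitat use, vertical
  stratum, diet, temporal activity) and log-normal biomass spanning a few
  grams to a few hundred grams, including one cluster of functionally
  near-redundant arboreal herbivores and one numerically dominant
  ground-dwelling granivore;
- seasonal rainfall with a strong wet/dry contrast (roughly 80% of the
  ~850 mm annual total falling in the wet season) and a single anomalously
  rainy dry season flagged by a dummy;
- seasonal total captures following a first-order negative-feedback
  (Gompertz-type) model on the log scale, driven by standardized seasonal
  precipitation, with counts allocated to species by a dominance-weighted
  multinomial. The dominant species takes ~90% of captures in the upland
  habitat and ~55% in the arroyo habitat; functionally extreme species
  receive the smallest shares (low evenness). Precipitation sensitivity
  and process noise are higher in the upland habitat, whose assemblage is
  correspondingly less stable.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from funcdyn.diversity import AssemblageSeries, SEASON_ORDER
from funcdyn.dynamics import ClimateSeries
from funcdyn.traits import TraitTable

__all__ = [
    "SimulationConfig",
    "simulate_trait_table",
    "simulate_climate",
    "simulate_abundance",
    "simulate_from_ar_model",
    "simulate_dataset",
]

DEFAULT_YEARS = tuple(range(1990, 2008)) + (2012,)

TRAIT_LEVELS = {
    "habitat": ["forest", "scrub", "grassland", "riparian"],
    "stratum": ["ground", "scansorial", "arboreal", "fossorial"],
    "diet": ["seeds", "fruit", "leaves", "insects", "vertebrates"],
    "activity": ["nocturnal", "crepuscular", "diurnal"],
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the monitored system: 13 species over the 1990-2007
    field years plus 2012, two habitats, dominant-species capture shares
    of 0.90 (upland) and 0.55 (arroyo), a wet season carrying ~80% of
    annual rainfall, one anomalously wet dry season (1992), and
    rate-of-change dynamics with first-order negative feedback.
    """

    n_species: int = 13
    years: tuple[int, ...] = DEFAULT_YEARS
    habitats: tuple[str, str] = ("arroyo", "upland")
    dominance: dict = field(
        default_factory=lambda: {"upland": 0.90, "arroyo": 0.55}
    )
    # climate (mm per season; degrees C)
    wet_ppt_mean: float = 680.0
    wet_ppt_sd: float = 240.0
    dry_ppt_mean: float = 170.0
    dry_ppt_sd: float = 80.0
    wet_tmean: float = 27.0
    dry_tmean: float = 24.0
    temp_sd: float = 0.8
    temp_halfrange: float = 7.0
    anomaly_year: int = 1992
    anomaly_season: str = "dry"
    anomaly_ppt_bonus: float = 600.0
    # abundance dynamics (log-scale totals)
    mean_total: dict = field(
        default_factory=lambda: {"upland": 120.0, "arroyo": 80.0}
    )
    beta_ppt: dict = field(default_factory=lambda: {"upland": 0.35, "arroyo": 0.15})
    gamma_feedback: float = -0.5
    sigma_process: dict = field(default_factory=lambda: {"upland": 0.45, "arroyo": 0.22})
    evenness_decay: float = 0.65  # geometric decay of non-dominant shares
    redundancy_cluster_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for h, d in self.dominance.items():
            if not 0.0 < d < 1.0:
                raise ValueError(f"dominance for {h!r} must lie in (0, 1)")
        if self.wet_ppt_mean <= self.dry_ppt_mean:
            raise ValueError("wet-season precipitation must exceed dry-season")
        for h, s in self.sigma_process.items():
            if s < 0:
                raise ValueError("process noise must be non-negative")

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


def _dirichlet_rows(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return rng.dirichlet(np.ones(k), size=n)


def simulate_trait_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> TraitTable:
    """Random compositional trait table with a planted redundancy cluster.

    Species 1 is the dominant ground-dwelling granivore (stratum and diet
    rows concentrated on ground/seeds). Species 2..(1+cluster size) form a
    near-identical cluster of mid-sized scansorial-arboreal herbivores,
    reproducing the low pairwise dissimilarity regime real assemblages
    show among redundant species. Biomass is log-normal across roughly
    4-300 g.
    """
    if cfg.n_species < 2:
        raise ValueError("need at least 2 species")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    species = cfg.species_ids()
    n = cfg.n_species

    categories: dict[str, pd.DataFrame] = {}
    rows_by_cat = {
        name: _dirichlet_rows(rng, n, len(levels))
        for name, levels in TRAIT_LEVELS.items()
    }

    # dominant species: ground-dwelling granivore, nocturnal
    def concentrate(row: np.ndarray, idx: int, mass: float = 0.85) -> np.ndarray:
        out = row * (1 - mass) / row.sum()
        out[idx] += mass
        return out / out.sum()

    rows_by_cat["stratum"][0] = concentrate(rows_by_cat["stratum"][0], 0)
    rows_by_cat["diet"][0] = concentrate(rows_by_cat["diet"][0], 0)
    rows_by_cat["activity"][0] = concentrate(rows_by_cat["activity"][0], 0)

    # redundancy cluster: near-identical arboreal herbivores
    c0, c1 = 1, min(1 + cfg.redundancy_cluster_size, n)
    for name in TRAIT_LEVELS:
        base = rows_by_cat[name][c0].copy()
        if name == "stratum":
            base = concentrate(base, 2)
        if name == "diet":
            base = concentrate(base, 2)
        for i in range(c0, c1):
            jitter = rng.normal(0.0, 0.01, size=base.shape)
            row = np.clip(base + jitter, 1e-4, None)
            rows_by_cat[name][i] = row / row.sum()

    for name, levels in TRAIT_LEVELS.items():
        categories[name] = pd.DataFrame(
            rows_by_cat[name], index=species, columns=levels
        )

    # biomass: dominant ~25 g, cluster ~35-40 g, rest log-normal 4-300 g
    log10_mass = rng.normal(1.35, 0.45, size=n)
    log10_mass = np.clip(log10_mass, math.log10(4.0), math.log10(300.0))
    log10_mass[0] = math.log10(25.0)
    log10_mass[c0:c1] = np.log10(rng.uniform(35.0, 40.0, size=c1 - c0))
    # guarantee the tail extremes exist (a shrew-sized and a skunk-sized one)
    if n >= 6:
        log10_mass[-1] = math.log10(rng.uniform(240.0, 300.0))
        log10_mass[-2] = math.log10(rng.uniform(4.0, 6.0))
    biomass = pd.Series(10.0**log10_mass, index=species, name="biomass_g")

    return TraitTable(species, categories, biomass)


def simulate_climate(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> ClimateSeries:
    """Seasonal climate series with one flagged rainfall anomaly."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for year in cfg.years:
        for season in ("dry", "wet"):
            if season == "wet":
                ppt = rng.normal(cfg.wet_ppt_mean, cfg.wet_ppt_sd)
                tmean = rng.normal(cfg.wet_tmean, cfg.temp_sd)
            else:
                ppt = rng.normal(cfg.dry_ppt_mean, cfg.dry_ppt_sd)
                tmean = rng.normal(cfg.dry_tmean, cfg.temp_sd)
            ppt = max(ppt, 0.0)
            yr92 = 0
            if year == cfg.anomaly_year and season == cfg.anomaly_season:
                ppt += cfg.anomaly_ppt_bonus
                yr92 = 1
            # diurnal range varies independently of the seasonal mean
            up = max(rng.normal(cfg.temp_halfrange, 1.0), 0.5)
            down = max(rng.normal(cfg.temp_halfrange, 1.0), 0.5)
            rows.append(
                {
                    "year": year,
                    "season": season,
                    "ppt_mm": ppt,
                    "tmean_c": tmean,
                    "tmax_c": tmean + up,
                    "tmin_c": tmean - down,
                    "yr92": yr92,
                }
            )
    return ClimateSeries(pd.DataFrame(rows))


def _species_shares(
    traits: TraitTable, dominance: float, decay: float
) -> np.ndarray:
    """Capture-probability vector: dominant share, then geometric decay.

    Non-dominant species are ordered by biomass extremity (distance of
    log10 mass from the non-dominant median), so functionally extreme
    species receive the smallest expected shares.
    """
    n = traits.n_species
    mass = np.log10(traits.biomass_g.to_numpy())
    others = np.arange(1, n)
    extremity = np.abs(mass[others] - np.median(mass[others]))
    order = others[np.argsort(extremity, kind="stable")]
    geo = decay ** np.arange(len(order))
    shares = np.empty(n)
    shares[0] = dominance
    shares[order] = (1.0 - dominance) * geo / geo.sum()
    return shares


def simulate_abundance(
    traits: TraitTable,
    climate: ClimateSeries,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> AssemblageSeries:
    """Seasonal capture counts from a log-scale feedback model.

    Per habitat, log expected total captures x_t evolves as

        x_t = x_{t-1} + alpha + beta * z_t + gamma * (x_{t-1} - mu) + sigma * eps_t

    where z_t is the standardized seasonal precipitation (relative to that
    season's configured mean and sd), gamma < 0 is first-order negative
    feedback toward the habitat carrying level mu, and eps is standard
    normal. Realized totals are Poisson draws around exp(x_t), allocated
    to species by a dominance-weighted multinomial.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    clim = climate.table.sort_values(
        ["year", "season"], key=lambda c: c.map(SEASON_ORDER) if c.name == "season" else c
    )
    species = traits.species_ids
    rows = []
    for habitat in cfg.habitats:
        shares = _species_shares(traits, cfg.dominance[habitat], cfg.evenness_decay)
        mu = math.log(cfg.mean_total[habitat])
        beta = cfg.beta_ppt[habitat]
        sigma = cfg.sigma_process[habitat]
        x = mu
        for rec in clim.itertuples(index=False):
            if rec.season == "wet":
                z = (rec.ppt_mm - cfg.wet_ppt_mean) / cfg.wet_ppt_sd
            else:
                z = (rec.ppt_mm - cfg.dry_ppt_mean) / cfg.dry_ppt_sd
            x = x + beta * z + cfg.gamma_feedback * (x - mu) + sigma * rng.normal()
            total = int(rng.poisson(math.exp(x)))
            counts = (
                rng.multinomial(total, shares) if total > 0 else np.zeros(len(species), int)
            )
            for sp, c in zip(species, counts):
                rows.append(
                    {
                        "year": rec.year,
                        "season": rec.season,
                        "habitat": habitat,
                        "species": sp,
                        "count": int(c),
                    }
                )
    frame = pd.DataFrame(rows)
    return AssemblageSeries(frame, mean_biomass_g=traits.biomass_g)


def simulate_from_ar_model(
    coefficients: np.ndarray,
    design: np.ndarray,
    sigma: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a response y = X @ beta + N(0, sigma) for recovery tests."""
    x = np.asarray(design, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    if x.ndim != 2 or x.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design {x.shape} incompatible with {beta.shape[0]} coefficients"
        )
    if not np.isfinite(x).all():
        raise ValueError("design matrix must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    return x @ beta + rng.normal(0.0, sigma, size=x.shape[0])


def simulate_dataset(
    cfg: SimulationConfig | None = None,
) -> tuple[TraitTable, ClimateSeries, AssemblageSeries]:
    """Generate the full default synthetic dataset from one config."""
    cfg = cfg or SimulationConfig()
    traits = simulate_trait_table(cfg)
    climate = simulate_climate(cfg)
    abundance = simulate_abundance(traits, climate, cfg)
    return traits, climate, abundance
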