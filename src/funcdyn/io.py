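"""Readers, writers, configuration, and the end-to-end pipeline.

File formats are plain CSV/JSON/Newick:

- traits: one row per species, columns ``species``,
  ``<category>__<level>`` proportion columns, ``biomass_g``;
- abundance: long format ``year,season,habitat,species,count`` (a
  ``month`` column, if present, is aggregated to seasons via the
  configurable month map; default wet = Jun-Oct, dry = Nov-May with the
  dry season assigned to the year of its Jan-May span);
- climate: ``year,season,ppt_mm,tmean_c,tmax_c,tmin_c[,yr92]``.

``run_all`` chains trait space -> FDis series -> null model -> dynamics
and writes tidy outputs plus a manifest recording config, seed, input
digests and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from funcdyn.diversity import AssemblageSeries, fd_series, embed_species
from funcdyn.dynamics import (
    ClimateSeries,
    ModelSpec,
    backward_select,
    build_predictors,
    fit_ols,
    merge_series,
    partial_r2,
    stepwise_improve,
    summarize_series,
)
from funcdyn.nullmodel import deviations, sfd_shape_summary, simulate_extinction_trajectories
from funcdyn.simulate import SimulationConfig, simulate_dataset
from funcdyn.traits import (
    TraitTable,
    build_trait_space,
    functional_dendrogram,
    validate_trait_table,
)

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "read_trait_csv",
    "write_trait_csv",
    "read_abundance_csv",
    "write_abundance_csv",
    "read_climate_csv",
    "write_climate_csv",
    "run_all",
]

log = logging.getLogger("funcdyn")

#: wet season spans June-October; dry November-May, labelled by the year
#: of the January-May span (so Nov/Dec belong to the *next* year's dry season)
DEFAULT_SEASON_OF_MONTH = {
    1: "dry", 2: "dry", 3: "dry", 4: "dry", 5: "dry",
    6: "wet", 7: "wet", 8: "wet", 9: "wet", 10: "wet",
    11: "dry", 12: "dry",
}

DEFAULT_CONFIG: dict = {
    "retention": 0.75,
    "normalize_traits": True,
    "linkage": "average",
    "n_traj": 1000,
    "seed": 1,
    "anomaly": {"year": 1992, "season": "dry"},
    "full_model_terms": {
        "dry": [
            "PPt", "PPt_1", "T_MEAN", "T_MIN", "YR92",
            "HAB", "HAB:PPt", "HAB:PPt_1", "Y_1", "Y_2", "logN",
        ],
        "wet": [
            "PPt", "PPt_1", "T_MEAN", "T_MIN",
            "HAB", "HAB:PPt", "HAB:PPt_1", "Y_1", "Y_2", "logN",
        ],
    },
    "fd_extra_terms": ["S_1"],
    "stepwise_candidates": ["T_MAX", "Year", "S_2"],
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config file over the package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


# ---------------------------------------------------------------- traits

def write_trait_csv(table: TraitTable, path: str | Path) -> None:
    cols = {}
    for name, block in table.categories.items():
        for level in block.columns:
            cols[f"{name}__{level}"] = block[level]
    frame = pd.DataFrame(cols, index=table.species_ids)
    frame.insert(0, "species", table.species_ids)
    frame["biomass_g"] = table.biomass_g
    frame.to_csv(path, index=False)


def read_trait_csv(path: str | Path) -> TraitTable:
    frame = pd.read_csv(path)
    if "species" not in frame.columns or "biomass_g" not in frame.columns:
        raise ValueError(f"{path}: trait CSV needs 'species' and 'biomass_g' columns")
    frame = frame.set_index("species")
    categories: dict[str, dict[str, pd.Series]] = {}
    for col in frame.columns:
        if col == "biomass_g":
            continue
        if "__" not in col:
            raise ValueError(
                f"{path}: unexpected column {col!r}; trait columns are "
                "'<category>__<level>'"
            )
        cat, level = col.split("__", 1)
        categories.setdefault(cat, {})[level] = frame[col]
    table = TraitTable(
        species_ids=list(frame.index),
        categories={c: pd.DataFrame(levels) for c, levels in categories.items()},
        biomass_g=frame["biomass_g"].astype(float),
    )
    return validate_trait_table(table)


# ------------------------------------------------------------- abundance

def read_abundance_csv(
    path: str | Path,
    season_of_month: dict[int, str] | None = None,
    mean_biomass_g: pd.Series | None = None,
) -> AssemblageSeries:
    frame = pd.read_csv(path)
    if "month" in frame.columns:
        mapping = season_of_month or DEFAULT_SEASON_OF_MONTH
        months = frame["month"].astype(int)
        unknown = set(months) - set(mapping)
        if unknown:
            raise ValueError(f"{path}: months without a season mapping: {sorted(unknown)}")
        frame = frame.copy()
        frame["season"] = months.map(mapping)
        # Nov/Dec belong to the following year's dry season
        rollover = (months >= 11) & (frame["season"] == "dry")
        frame.loc[rollover, "year"] = frame.loc[rollover, "year"] + 1
        frame = (
            frame.groupby(["year", "season", "habitat", "species"], as_index=False)[
                "count"
            ].sum()
        )
    needed = ["year", "season", "habitat", "species", "count"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: abundance CSV missing columns {missing}")
    frame = frame[needed].copy()
    frame["season"] = frame["season"].str.lower()
    bad = ~frame["season"].isin(["dry", "wet"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown season labels at rows {list(frame.index[bad][:5])}"
        )
    dup = frame.duplicated(["year", "season", "habitat", "species"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (year,season,habitat,species) at rows "
            f"{list(frame.index[dup][:5])}"
        )
    return AssemblageSeries(frame, mean_biomass_g=mean_biomass_g)


def write_abundance_csv(assemblages: AssemblageSeries, path: str | Path) -> None:
    assemblages.counts.to_csv(path, index=False)


# --------------------------------------------------------------- climate

def read_climate_csv(
    path: str | Path, anomaly: dict | None = None
) -> ClimateSeries:
    frame = pd.read_csv(path)
    frame.columns = [c.lower() for c in frame.columns]
    needed = ["year", "season", "ppt_mm", "tmean_c", "tmax_c", "tmin_c"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: climate CSV missing columns {missing}")
    frame["season"] = frame["season"].str.lower()
    if "yr92" not in frame.columns:
        anomaly = anomaly or {"year": 1992, "season": "dry"}
        frame["yr92"] = (
            (frame["year"] == anomaly["year"]) & (frame["season"] == anomaly["season"])
        ).astype(int)
    return ClimateSeries(frame)


def write_climate_csv(climate: ClimateSeries, path: str | Path) -> None:
    climate.table.to_csv(path, index=False)


# ----------------------------------------------------------- diagnostics

def plot_sfd_deviations(curve, estimates: pd.DataFrame, path: Path) -> None:
    """Null SFD band with observed occurrence-based FDis overplotted."""
    frame = curve.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(frame["r"], frame["q025"], frame["q975"], alpha=0.25,
                    color="grey", label="null 95% band")
    ax.plot(frame["r"], frame["mean"], color="black", label="null mean (SFD)")
    for habitat, marker in zip(sorted(estimates["habitat"].unique()), "ox"):
        sub = estimates[estimates["habitat"] == habitat]
        ax.scatter(sub["S"], sub["FDo"], marker=marker, s=18, label=f"FDo {habitat}")
    ax.set_xlabel("species richness S")
    ax.set_ylabel("FDis")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_residuals(residuals: pd.DataFrame, path: Path) -> None:
    """Per-model residuals against year, for human inspection."""
    pairs = sorted(set(zip(residuals["response"], residuals["season"])))
    fig, axes = plt.subplots(2, 4, figsize=(12, 5), sharex=True)
    for ax, (response, season) in zip(axes.ravel(), pairs):
        sub = residuals[
            (residuals["response"] == response) & (residuals["season"] == season)
        ]
        for habitat, marker in zip(sorted(sub["habitat"].unique()), "ox"):
            h = sub[sub["habitat"] == habitat]
            ax.scatter(h["year"], h["residual"], marker=marker, s=12)
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_title(f"{response} / {season}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -------------------------------------------------------------- pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _full_spec(response: str, season: str, config: dict) -> ModelSpec:
    terms = list(config["full_model_terms"][season])
    if response != "dS":
        terms += [t for t in config["fd_extra_terms"] if t not in terms]
    return ModelSpec(response=response, season=season, terms=tuple(terms))


def select_model(
    climate: ClimateSeries,
    merged: pd.DataFrame,
    response: str,
    season: str,
    config: dict,
) -> dict:
    """Backward + stepwise AICc selection for one response x season."""
    full = _full_spec(response, season, config)
    # materialize the stepwise candidate columns alongside the full model's,
    # so every model in the search is compared on one common row set
    probe = ModelSpec(
        response=response,
        season=season,
        terms=tuple(
            dict.fromkeys(list(full.terms) + list(config["stepwise_candidates"]))
        ),
    )
    data = build_predictors(climate, merged, probe)
    selected, trace = backward_select(full, data)
    pool = list(dict.fromkeys(list(full.terms) + list(config["stepwise_candidates"])))
    selected, trace = stepwise_improve(selected, pool, data, trace)
    fit = fit_ols(data, selected, keep_residuals=True)
    pr2 = partial_r2(fit, data)
    return {
        "response": response,
        "season": season,
        "terms": list(selected.terms),
        "coefficients": fit.params.to_dict(),
        "standard_errors": fit.bse.to_dict(),
        "sigma": fit.sigma,
        "n": fit.n,
        "k": fit.k,
        "rss": fit.rss,
        "r2": fit.r2,
        "aicc": fit.aicc,
        "partial_r2": pr2.to_dict(),
        "selection_trace": trace.steps,
        "_residuals": fit.residuals,
        "_data_index": data[["year", "habitat"]],
    }


def run_all(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "runs",
    seed: int | None = None,
    traits: TraitTable | None = None,
    climate: ClimateSeries | None = None,
    abundance: AssemblageSeries | None = None,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """Execute the full analysis and write all stage outputs.

    If no inputs are supplied, the default synthetic dataset is generated
    from the seed. Returns the manifest (also written to
    ``<out_dir>/manifest.json``).
    """
    t0 = time.time()
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config["seed"] = seed
    seed = int(config["seed"])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _save_df(frame: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        frame.to_csv(path, **kw)
        outputs[name] = str(path)

    # stage 0: inputs
    stage = time.time()
    synthetic = traits is None or climate is None or abundance is None
    if synthetic:
        cfg = sim_config or SimulationConfig(seed=seed)
        traits, climate, abundance = simulate_dataset(cfg)
        log.info("generated synthetic dataset (seed=%d)", seed)
    if abundance.mean_biomass_g is None:
        abundance = AssemblageSeries(abundance.counts, mean_biomass_g=traits.biomass_g)
    timings["inputs"] = time.time() - stage

    # stage 1: trait space
    stage = time.time()
    traits = validate_trait_table(traits)
    fd = build_trait_space(
        traits,
        retention=float(config["retention"]),
        normalize=bool(config["normalize_traits"]),
    )
    _save_df(fd.G, "dissimilarity_G.csv")
    dendro = functional_dendrogram(fd, linkage=config["linkage"])
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    outputs["dendrogram.nwk"] = str(out / "dendrogram.nwk")
    timings["trait_space"] = time.time() - stage

    # stage 2: FDis series
    stage = time.time()
    coords = embed_species(fd)
    estimates = fd_series(abundance, fd, coords=coords)
    _save_df(estimates, "fdis_series.csv", index=False)
    timings["functional_diversity"] = time.time() - stage

    # stage 3: null model
    stage = time.time()
    curve = simulate_extinction_trajectories(
        fd, n_traj=int(config["n_traj"]), seed=seed
    )
    _save_df(curve.to_frame(), "null_curve.csv", index=False)
    dev = deviations(estimates, curve)
    _save_df(dev, "deviations.csv", index=False)
    shape = sfd_shape_summary(curve)
    timings["null_model"] = time.time() - stage

    # stage 4: dynamics
    stage = time.time()
    merged = merge_series(estimates, dev)
    models = []
    residual_rows = []
    for response in ("dS", "dFDo", "dFDn", "dFDw"):
        for season in ("dry", "wet"):
            result = select_model(climate, merged, response, season, config)
            resid = result.pop("_residuals")
            ridx = result.pop("_data_index")
            if resid is not None:
                for (year, habitat), r in zip(
                    ridx.itertuples(index=False), resid.to_numpy()
                ):
                    residual_rows.append(
                        {
                            "response": response,
                            "season": season,
                            "year": year,
                            "habitat": habitat,
                            "residual": r,
                        }
                    )
            models.append(result)
            log.info(
                "selected %s/%s: terms=%s AICc=%.2f R2=%.3f",
                response, season, result["terms"], result["aicc"], result["r2"],
            )
    (out / "models.json").write_text(json.dumps(models, indent=2, default=float))
    outputs["models.json"] = str(out / "models.json")
    residual_frame = pd.DataFrame(residual_rows)
    _save_df(residual_frame, "residuals.csv", index=False)
    plot_sfd_deviations(curve, estimates, out / "sfd_deviations.png")
    plot_residuals(residual_frame, out / "residual_diagnostics.png")
    outputs["sfd_deviations.png"] = str(out / "sfd_deviations.png")
    outputs["residual_diagnostics.png"] = str(out / "residual_diagnostics.png")
    timings["dynamics"] = time.time() - stage

    # stage 5: summaries
    habitats = sorted(abundance.counts["habitat"].unique())
    summaries = {h: summarize_series(estimates, h) for h in habitats}
    pooled = abundance.counts.groupby("species")["count"].sum()
    dominance = {}
    for h in habitats:
        per = abundance.counts[abundance.counts["habitat"] == h]
        tot = per.groupby("species")["count"].sum()
        dominance[h] = float(tot.max() / tot.sum()) if tot.sum() else float("nan")
    summary = {
        "species_pool": int((pooled > 0).sum()),
        "dominant_species": str(pooled.idxmax()),
        "dominance_share": dominance,
        "cv": summaries,
        "saturation_index": shape["saturation_index"],
        "pool_fdis": curve.pool_fdis,
        "n_models": len(models),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    outputs["summary.json"] = str(out / "summary.json")

    manifest = {
        "package_version": __import__("funcdyn").__version__,
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "synthetic_inputs": synthetic,
        "outputs": outputs,
        # digests cover the numeric outputs; figures are for human review
        "output_digests": {
            k: _sha256(Path(v)) for k, v in outputs.items() if not k.endswith(".png")
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t0, 3),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    for name in outputs:
        assert (out / name).exists()
    return manifest
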