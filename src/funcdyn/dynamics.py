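"""Autoregressive driver models for biodiversity rates of change.

Biodiversity is modelled on the scale of its seasonal rate of change,

    dY_t = Y_t - Y_{t-1} = alpha + B.X_t + betaH.HAB_t + I.(HAB_t.X_t) + eps,

with eps ~ N(0, sigma). Including the previous-season level Y_{t-1} as a
predictor makes the model autoregressive: a negative coefficient is
first-order negative feedback (regulation). Species richness, a count, is
differenced on the log scale, dS_t = log(S_t / S_{t-1}); functional
diversity enters as the deviation from the null-model expectation, so its
rate of change isolates the extrinsic (non-richness-mediated) component.

Candidate drivers are current- and previous-season precipitation, seasonal
mean/max/min temperature, an anomalous-rainfall dummy, habitat and its
interactions with the drivers, lagged biodiversity (previous season, and
the same season one year back), log total captures as a sample-size
covariate, and optionally a linear Year trend. Models are fitted by
ordinary least squares per season with both habitats stacked; model choice
is backward elimination followed by stepwise refinement under AICc, and
predictor importance is the partial coefficient of determination
R2_X = R2 - R2_{-X}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from funcdyn.diversity import SEASON_ORDER, SEASONS

__all__ = [
    "ClimateSeries",
    "ModelSpec",
    "FitResult",
    "SelectionTrace",
    "merge_series",
    "build_response",
    "build_predictors",
    "fit_ols",
    "aicc",
    "backward_select",
    "stepwise_improve",
    "partial_r2",
    "summarize_series",
]

RESPONSES = ("dS", "dFDo", "dFDn", "dFDw")

#: columns build_predictors can materialize (besides interactions)
MAIN_TERMS = (
    "PPt",
    "PPt_1",
    "T_MEAN",
    "T_MAX",
    "T_MIN",
    "YR92",
    "HAB",
    "Y_1",
    "Y_2",
    "S_1",
    "S_2",
    "logN",
    "Year",
)


@dataclass
class ClimateSeries:
    """Seasonal climate: precipitation, temperatures, anomaly dummy.

    ``table`` columns: ``year, season, ppt_mm, tmean_c, tmax_c, tmin_c,
    yr92``. The dry season is labelled by the year containing its Jan-May
    span; ``yr92`` is 1 only for the flagged anomalous season-year.
    """

    table: pd.DataFrame

    REQUIRED = ("year", "season", "ppt_mm", "tmean_c", "tmax_c", "tmin_c", "yr92")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        t = self.table
        if (t["ppt_mm"] < 0).any():
            raise ValueError("precipitation must be non-negative")
        bad = ~((t["tmin_c"] <= t["tmean_c"]) & (t["tmean_c"] <= t["tmax_c"]))
        if bad.any():
            raise ValueError(
                f"temperature ordering violated at rows {list(t.index[bad])}"
            )
        if t.duplicated(["year", "season"]).any():
            raise ValueError("duplicate (year, season) climate rows")

    def lookup(self, year: int, season: str) -> pd.Series | None:
        m = (self.table["year"] == year) & (self.table["season"] == season)
        sub = self.table[m]
        return None if sub.empty else sub.iloc[0]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response kind, season, and predictor terms.

    Terms are column labels; interactions are ``"HAB:<main>"`` and may
    appear only alongside both parents (marginality). The intercept is
    implicit.
    """

    response: str
    season: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects in the model"
                    )

    def with_terms(self, terms) -> "ModelSpec":
        return replace(self, terms=tuple(terms))


@dataclass
class FitResult:
    """An OLS fit with AICc bookkeeping (k counts coefficients + sigma)."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    sigma: float
    n: int
    k: int
    rss: float
    r2: float
    aicc: float
    residuals: pd.Series | None = None


@dataclass
class SelectionTrace:
    """Log of every candidate model examined during selection."""

    steps: list[dict] = field(default_factory=list)

    def log(self, action: str, term: str, aicc_value: float, accepted: bool) -> None:
        self.steps.append(
            {"action": action, "term": term, "aicc": aicc_value, "accepted": accepted}
        )


def _season_index(year: int, season: str) -> int:
    """Consecutive integer over (year, season) in chronological order."""
    return int(year) * 2 + SEASON_ORDER[season]


def merge_series(fd_estimates: pd.DataFrame, dev: pd.DataFrame) -> pd.DataFrame:
    """Join the FDis series with its null-model deviations on record keys."""
    return fd_estimates.merge(dev, on=["year", "season", "habitat", "S"], how="left")


_RESPONSE_LEVEL = {"dS": "S", "dFDo": "dFDo", "dFDn": "dFDn", "dFDw": "dFDw"}


def build_response(series: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Seasonal rate of change of a biodiversity parameter per habitat.

    ``series`` is the merged biodiversity frame (columns ``year, season,
    habitat, S, total_captures, dFDo, dFDn, dFDw``). Richness is
    differenced on the log scale (``dS = log(S_t/S_{t-1})``); deviations
    arithmetically. A transition is valid only if the chronologically
    previous season is present for the same habitat (monitoring gaps break
    the chain); transitions with S = 0 on either end are flagged missing.
    """
    if kind not in RESPONSES:
        raise ValueError(f"kind must be one of {RESPONSES}")
    level = _RESPONSE_LEVEL[kind]
    df = series.copy()
    df["t"] = [_season_index(y, s) for y, s in zip(df["year"], df["season"])]
    rows = []
    for habitat, sub in df.groupby("habitat"):
        sub = sub.sort_values("t").set_index("t")
        for t, rec in sub.iterrows():
            prev = sub.loc[t - 1] if (t - 1) in sub.index else None
            if prev is None:
                continue
            if kind == "dS":
                if rec["S"] <= 0 or prev["S"] <= 0:
                    value = np.nan
                else:
                    value = math.log(rec["S"] / prev["S"])
            else:
                value = rec[level] - prev[level]
            rows.append(
                {
                    "year": int(rec["year"]),
                    "season": rec["season"],
                    "habitat": habitat,
                    "y": value,
                }
            )
    return pd.DataFrame(rows)


def build_predictors(
    climate: ClimateSeries,
    series: pd.DataFrame,
    spec: ModelSpec,
    habitat_reference: str | None = None,
) -> pd.DataFrame:
    """Assemble the model frame (response ``y`` plus term columns).

    Rows are (year, habitat) records of the spec's season, both habitats
    stacked. ``PPt_1`` is the previous season's precipitation (the same
    year's dry season for a wet-season model; the previous year's wet
    season for a dry-season model). ``Y_1``/``Y_2`` are the response
    parameter's level at the previous season and the same season one year
    back (log richness for the richness model, the null-model deviation
    for functional-diversity models); ``S_1``/``S_2`` are lagged richness
    for use in functional-diversity models. Habitat is coded 0/1 with the
    alphabetically first habitat as reference unless overridden. Rows with
    any missing requested predictor are dropped.
    """
    level = _RESPONSE_LEVEL[spec.response]
    resp = build_response(series, spec.response)
    habitats = sorted(series["habitat"].unique())
    if habitat_reference is None:
        habitat_reference = habitats[0]

    df = series.copy()
    df["t"] = [_season_index(y, s) for y, s in zip(df["year"], df["season"])]
    by_habitat = {
        h: sub.sort_values("t").set_index("t") for h, sub in df.groupby("habitat")
    }
    clim = climate.table.copy()
    clim["t"] = [_season_index(y, s) for y, s in zip(clim["year"], clim["season"])]
    clim = clim.set_index("t")

    def level_at(habitat: str, t: int, col: str):
        sub = by_habitat[habitat]
        if t not in sub.index:
            return np.nan
        rec = sub.loc[t]
        if col == "S_log":
            return math.log(rec["S"]) if rec["S"] > 0 else np.nan
        return rec[col]

    rows = []
    for rec in resp.itertuples(index=False):
        if rec.season != spec.season:
            continue
        t = _season_index(rec.year, rec.season)
        row: dict = {"year": rec.year, "habitat": rec.habitat, "y": rec.y}
        if t in clim.index:
            c = clim.loc[t]
            row["PPt"] = c["ppt_mm"]
            row["T_MEAN"] = c["tmean_c"]
            row["T_MAX"] = c["tmax_c"]
            row["T_MIN"] = c["tmin_c"]
            row["YR92"] = c["yr92"]
        if (t - 1) in clim.index:
            row["PPt_1"] = clim.loc[t - 1]["ppt_mm"]
        row["HAB"] = 0.0 if rec.habitat == habitat_reference else 1.0
        lag_col = "S_log" if spec.response == "dS" else level
        row["Y_1"] = level_at(rec.habitat, t - 1, lag_col)
        row["Y_2"] = level_at(rec.habitat, t - 2, lag_col)
        row["S_1"] = level_at(rec.habitat, t - 1, "S")
        row["S_2"] = level_at(rec.habitat, t - 2, "S")
        n_tot = level_at(rec.habitat, t, "total_captures")
        row["logN"] = math.log(n_tot) if n_tot and n_tot > 0 else np.nan
        row["Year"] = float(rec.year)
        rows.append(row)

    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError(f"no records for season {spec.season!r}")
    for term in spec.terms:
        if ":" in term:
            a, b = term.split(":")
            frame[term] = frame[a] * frame[b]
        elif term not in frame.columns:
            raise KeyError(f"no data column for term {term!r}")
    needed = ["y", *spec.terms]
    kept = frame.dropna(subset=needed)
    return kept.reset_index(drop=True)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian OLS fit.

    ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`` where k counts every
    regression coefficient (intercept included) plus one for the residual
    variance. Undefined for n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    if rss <= 0:
        raise ValueError("RSS must be positive")
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def fit_ols(data: pd.DataFrame, spec: ModelSpec, keep_residuals: bool = False) -> FitResult:
    """Ordinary least squares of ``y`` on the spec's terms plus intercept."""
    y = data["y"].to_numpy(dtype=float)
    cols = ["Intercept", *spec.terms]
    x = np.column_stack(
        [np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in spec.terms]
    )
    n, p = x.shape
    k = p + 1  # + residual variance
    if n <= k + 1:
        raise ValueError(
            f"too few observations (n={n}) for {p} coefficients plus variance"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"design is rank-deficient (rank {rank} < {p} columns): "
            f"check collinearity among {cols}"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - p
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    bse = np.sqrt(np.diag(xtx_inv) * sigma2)
    return FitResult(
        spec=spec,
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        sigma=math.sqrt(sigma2),
        n=n,
        k=k,
        rss=rss,
        r2=r2,
        aicc=aicc(max(rss, 1e-300), n, k),
        residuals=pd.Series(resid, index=data.index) if keep_residuals else None,
    )


def _removable(terms: tuple[str, ...]) -> list[str]:
    """Terms deletable now: interactions always; mains only once free."""
    interactions = [t for t in terms if ":" in t]
    locked = {p for t in interactions for p in t.split(":")}
    return interactions + [t for t in terms if ":" not in t and t not in locked]


def _addable(terms: tuple[str, ...], candidates) -> list[str]:
    out = []
    for t in candidates:
        if t in terms:
            continue
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                continue
        out.append(t)
    return out


def backward_select(
    full: ModelSpec, data: pd.DataFrame, trace: SelectionTrace | None = None
) -> tuple[ModelSpec, SelectionTrace]:
    """Backward elimination under AICc.

    Starting from the full model, repeatedly deletes the single removable
    term (interactions before the main effects they contain) whose removal
    most lowers AICc; stops when no deletion improves. Ties favour the
    deletion leaving fewer parameters, then lexicographic term order.
    """
    trace = trace or SelectionTrace()
    current = full
    current_fit = fit_ols(data, current)
    while True:
        best: tuple[float, int, str, ModelSpec] | None = None
        for term in sorted(_removable(current.terms)):
            cand = current.with_terms(t for t in current.terms if t != term)
            fit = fit_ols(data, cand)
            trace.log("drop", term, fit.aicc, False)
            key = (fit.aicc, len(cand.terms), term)
            if best is None or key < best[:3]:
                best = (*key, cand)
        if best is None or best[0] >= current_fit.aicc - 1e-12:
            return current, trace
        _, _, term, current = best
        current_fit = fit_ols(data, current)
        trace.log("drop", term, current_fit.aicc, True)


def stepwise_improve(
    selected: ModelSpec,
    candidates,
    data: pd.DataFrame,
    trace: SelectionTrace | None = None,
) -> tuple[ModelSpec, SelectionTrace]:
    """Stepwise refinement: alternating add/drop moves under AICc.

    At each round, evaluates every admissible single-term addition from
    the candidate pool and every admissible deletion, accepting the move
    that most lowers AICc. Terminates when no move improves (AICc strictly
    decreases, so the walk cannot cycle).
    """
    trace = trace or SelectionTrace()
    candidates = list(candidates)
    current = selected
    current_fit = fit_ols(data, current)
    while True:
        best: tuple[float, int, str, str, ModelSpec] | None = None
        moves = [("add", t) for t in _addable(current.terms, candidates)] + [
            ("drop", t) for t in _removable(current.terms)
        ]
        for action, term in sorted(moves, key=lambda m: (m[0], m[1])):
            if action == "add":
                cand = current.with_terms((*current.terms, term))
            else:
                cand = current.with_terms(t for t in current.terms if t != term)
            try:
                fit = fit_ols(data, cand)
            except (ValueError, np.linalg.LinAlgError):
                continue
            trace.log(action, term, fit.aicc, False)
            key = (fit.aicc, len(cand.terms), term)
            if best is None or key < best[:3]:
                best = (*key, action, cand)
        if best is None or best[0] >= current_fit.aicc - 1e-12:
            return current, trace
        aicc_val, _, term, action, current = best
        current_fit = fit_ols(data, current)
        trace.log(action, term, current_fit.aicc, True)


def partial_r2(fit: FitResult, data: pd.DataFrame) -> pd.Series:
    """Partial determination coefficient per main-effect predictor.

    For each main effect X in the model, refits without X and every
    interaction containing X; ``R2_X = R2 - R2_{-X}``. If removal empties
    the model the comparison is against the intercept-only fit (R2 = 0).
    """
    out = {}
    mains = [t for t in fit.spec.terms if ":" not in t]
    for x in mains:
        reduced_terms = tuple(
            t for t in fit.spec.terms if t != x and x not in t.split(":")
        )
        if reduced_terms:
            reduced = fit_ols(data, fit.spec.with_terms(reduced_terms))
            r2_minus = reduced.r2
        else:
            r2_minus = 0.0
        out[x] = fit.r2 - r2_minus
    return pd.Series(out, name="partial_r2")


def summarize_series(fd_estimates: pd.DataFrame, habitat: str) -> dict:
    """Variability summary of the functional-diversity series for a habitat.

    Reports the coefficient of variation (CV = 100 * sd / mean, sample sd)
    of the pooled FDo/FDn/FDw values across all seasons and years, the CV
    of each index separately, and their average -- two conventions for
    collapsing three indices into one habitat-level variability figure.
    """
    sub = fd_estimates[fd_estimates["habitat"] == habitat]
    pooled = (
        pd.concat([sub["FDo"], sub["FDn"], sub["FDw"]]).dropna().to_numpy()
    )
    if pooled.size < 2:
        raise ValueError(f"not enough finite values for habitat {habitat!r}")
    mean = pooled.mean()
    if mean == 0:
        raise ValueError("mean of pooled series is zero; CV undefined")
    cv_pooled = 100.0 * pooled.std(ddof=1) / mean
    per_index = {}
    for col in ("FDo", "FDn", "FDw"):
        v = sub[col].dropna().to_numpy()
        if v.size >= 2 and v.mean() != 0:
            per_index[col] = 100.0 * v.std(ddof=1) / v.mean()
        else:
            per_index[col] = np.nan
    return {
        "habitat": habitat,
        "cv_pooled": float(cv_pooled),
        "cv_per_index": per_index,
        "cv_mean_of_indices": float(np.nanmean(list(per_index.values()))),
        "n_records": int(len(sub)),
    }
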