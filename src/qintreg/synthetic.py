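"""Seeded DHS-like synthetic data with analytically known quantile structure.

Real child-anthropometry microdata (Demographic and Health Surveys) are
restricted, so every downstream stage of the pipeline is exercised on
synthetic tables that copy the *shape* of such data: a BMI-for-age z-score
outcome (BMIAZ), binary household/child covariates, wealth quintile and
maternal education factors, child age in months (0–59), preceding birth
interval (PBI, missing for first-borns), a region label on a 13-region map,
and three survey years with the wealth quintile entirely missing in the first
year (2000), as in the Namibia surveys.

The outcome follows a Gaussian location-scale model

    y = mu(x) + sigma(x) * eps,   eps ~ N(0,1),
    mu(x)        = beta0 + x'beta_loc + g_age(age) + g_pbi(pbi)
                   + u_region + v_year,
    log sigma(x) = gamma0 + x'gamma_scale,

so every conditional quantile is available in closed form,

    Q_tau(y | x) = mu(x) + Phi^{-1}(tau) * sigma(x),

which gives analytic targets for quantile-regression recovery tests.  The
regional field ``u`` is an ICAR draw (centred to sum to zero) and the year
effect ``v`` a centred first-order random walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .gmrf import LatentSpec, build_latent_precision, sample_constrained_gmrf
from .graphs import RegionGraph

__all__ = [
    "GeneratorConfig",
    "AnalysisDataset",
    "true_quantile_surface",
    "true_fixed_effect",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

# covariates whose dummies carry these labels in the fitted models
BINARY_COVARIATES = (
    "urban", "improved_water", "improved_toilet", "television",
    "male_head", "male_child",
)
WEALTH_LEVELS = ("poorest", "poorer", "middle", "richer", "richest")
EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")


def _default_prevalences() -> dict[str, Any]:
    return {
        "urban": 0.48,
        "improved_water": 0.80,
        "improved_toilet": 0.45,
        "television": 0.35,
        "male_head": 0.55,
        "male_child": 0.51,
        "wealth": {lv: 0.2 for lv in WEALTH_LEVELS},
        "education": {"none": 0.12, "primary": 0.35,
                      "secondary": 0.45, "higher": 0.08},
    }


def _default_location_effects() -> dict[str, float]:
    # modest positive effects on the z-score location, in z-score units
    return {
        "urban": 0.25, "improved_water": 0.10, "improved_toilet": 0.08,
        "television": 0.12, "male_head": 0.05, "male_child": 0.08,
        "wealth=poorer": 0.05, "wealth=middle": 0.10,
        "wealth=richer": 0.18, "wealth=richest": 0.30,
        "education=primary": 0.05, "education=secondary": 0.12,
        "education=higher": 0.20,
    }


def _default_logscale_effects() -> dict[str, float]:
    # a single covariate widens the residual scale, so the tau-quantile
    # contrast of every dummy stays exactly additive (see docs/methods.md)
    return {"urban": 0.15}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic DHS-like generator.

    ``covariate_prevalences`` maps a binary covariate name to its Bernoulli
    probability, and a factor name (``wealth``, ``education``) to a
    level->probability mapping whose first level is the reference.
    ``fixed_effect_location`` / ``fixed_effect_logscale`` are keyed by dummy
    label: the bare name for binary covariates, ``"name=level"`` for factors.
    """

    n_per_year: int = 1500
    years: tuple[int, ...] = (2000, 2006, 2013)
    covariate_prevalences: Mapping[str, Any] = field(
        default_factory=_default_prevalences)
    fixed_effect_location: Mapping[str, float] = field(
        default_factory=_default_location_effects)
    fixed_effect_logscale: Mapping[str, float] = field(
        default_factory=_default_logscale_effects)
    # chosen so that with the default covariate mix (mean contribution of
    # covariates and curves ~ +0.8 z-units) the combined overweight/obesity
    # prevalence sits in the low single digits, as in the emulated surveys
    intercept_location: float = -0.4
    intercept_logscale: float = 0.0
    age_curve_params: Mapping[str, Any] = field(default_factory=lambda: {
        "shape": "inverse_u", "peak": 24.0, "height": 0.35, "halfwidth": 30.0})
    pbi_curve_params: Mapping[str, Any] = field(default_factory=lambda: {
        "shape": "sigmoid_decreasing", "center": 48.0, "scale": 12.0,
        "height": 0.30})
    firstborn_prob: float = 0.25
    wealth_missing_years: tuple[int, ...] = (2000,)
    spatial_precision: float | None = 4.0
    temporal_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be >= 1")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        for name, p in self.covariate_prevalences.items():
            probs = list(p.values()) if isinstance(p, Mapping) else [p]
            if any(not 0 <= q <= 1 for q in probs):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
            if isinstance(p, Mapping) and abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"level probabilities for {name!r} must sum to 1")
        if not 0 <= self.firstborn_prob <= 1:
            raise ValueError("firstborn_prob outside [0, 1]")
        if self.spatial_precision is not None and self.spatial_precision <= 0:
            raise ValueError("spatial_precision must be > 0")
        if self.temporal_sd < 0:
            raise ValueError("temporal_sd must be >= 0")

    # -- truth curves -----------------------------------------------------
    def age_curve(self, age: np.ndarray | float) -> np.ndarray | float:
        p = dict(self.age_curve_params)
        shape = p.get("shape", "inverse_u")
        age = np.asarray(age, dtype=float)
        if shape == "inverse_u":
            return p["height"] * (1.0 - ((age - p["peak"]) / p["halfwidth"]) ** 2)
        if shape == "linear":
            return p.get("slope", 0.01) * (age - 30.0)
        if shape == "zero":
            return np.zeros_like(age)
        raise ValueError(f"unknown age curve shape {shape!r}")

    def pbi_curve(self, pbi: np.ndarray | float) -> np.ndarray | float:
        p = dict(self.pbi_curve_params)
        shape = p.get("shape", "sigmoid_decreasing")
        pbi = np.asarray(pbi, dtype=float)
        if shape == "sigmoid_decreasing":
            return p["height"] * (
                1.0 / (1.0 + np.exp((pbi - p["center"]) / p["scale"])) - 0.5)
        if shape == "zero":
            return np.zeros_like(pbi)
        raise ValueError(f"unknown PBI curve shape {shape!r}")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = asdict(self)
        doc["years"] = list(self.years)
        doc["wealth_missing_years"] = list(self.wealth_missing_years)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("years", "wealth_missing_years"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def intercept_only(cls, n_per_year: int = 1500, seed: int = 0,
                       **kwargs: Any) -> "GeneratorConfig":
        """Pure location-scale noise: no covariate, curve, spatial or year effects."""
        return cls(
            n_per_year=n_per_year,
            covariate_prevalences={},
            fixed_effect_location={},
            fixed_effect_logscale={},
            age_curve_params={"shape": "zero"},
            pbi_curve_params={"shape": "zero"},
            spatial_precision=None,
            temporal_sd=0.0,
            seed=seed,
            **kwargs,
        )


@dataclass
class AnalysisDataset:
    """Child-level analysis table plus generator truth metadata (if synthetic).

    ``df`` columns: ``bmiaz`` (float, never missing), the categorical
    covariates, ``child_age_months`` (int 0–59), ``preceding_birth_interval
    _months`` (nullable int, missing = first-born), ``region_id``, ``year``.
    """

    df: pd.DataFrame
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if "bmiaz" in self.df.columns and self.df["bmiaz"].isna().any():
            raise ValueError("bmiaz must not be missing")

    def __len__(self) -> int:
        return len(self.df)


def _dummy_labels(config: GeneratorConfig) -> list[str]:
    labels = []
    for name, p in config.covariate_prevalences.items():
        if isinstance(p, Mapping):
            labels += [f"{name}={lv}" for lv in list(p)[1:]]
        else:
            labels.append(name)
    return labels


def _predictors(config: GeneratorConfig, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Location and log-scale linear predictors excluding latent effects."""
    n = len(df)
    loc = np.full(n, config.intercept_location)
    lsc = np.full(n, config.intercept_logscale)
    for name, p in config.covariate_prevalences.items():
        if name not in df.columns:  # absent covariate = reference level
            continue
        if isinstance(p, Mapping):
            for lv in list(p)[1:]:
                ind = (df[name] == lv).to_numpy(dtype=float)
                # wholly-missing years contribute nothing
                ind[df[name].isna().to_numpy()] = 0.0
                loc += config.fixed_effect_location.get(f"{name}={lv}", 0.0) * ind
                lsc += config.fixed_effect_logscale.get(f"{name}={lv}", 0.0) * ind
        else:
            ind = df[name].to_numpy(dtype=float)
            loc += config.fixed_effect_location.get(name, 0.0) * ind
            lsc += config.fixed_effect_logscale.get(name, 0.0) * ind
    loc = loc + np.asarray(config.age_curve(df["child_age_months"].to_numpy()))
    pbi = df["preceding_birth_interval_months"]
    has_pbi = pbi.notna().to_numpy()
    g_pbi = np.zeros(n)
    if has_pbi.any():
        g_pbi[has_pbi] = np.asarray(
            config.pbi_curve(pbi[has_pbi].to_numpy(dtype=float)))
    return loc + g_pbi, lsc


def true_quantile_surface(
    config: GeneratorConfig,
    covariates: Mapping[str, Any],
    tau: float,
    latent_effects: Mapping[str, Mapping[Any, float]] | None = None,
) -> float:
    """Closed-form conditional tau-quantile of the generator.

    ``covariates`` is a single record (covariate name -> value, plus
    ``child_age_months`` and optionally ``preceding_birth_interval_months``,
    ``region_id`` and ``year``).  Latent region/year effects are added when
    ``latent_effects`` (as attached to a generated dataset's ``truth``) is
    supplied and the record names a region/year.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    rec = dict(covariates)
    rec.setdefault("child_age_months", 0)
    rec.setdefault("preceding_birth_interval_months", np.nan)
    df = pd.DataFrame([rec])
    loc, lsc = _predictors(config, df)
    mu, sigma = float(loc[0]), float(np.exp(lsc[0]))
    if latent_effects is not None:
        if "region_id" in rec and rec["region_id"] is not None:
            mu += latent_effects["region"].get(rec["region_id"], 0.0)
        if "year" in rec and rec["year"] is not None:
            mu += latent_effects["year"].get(rec["year"], 0.0)
    return mu + norm.ppf(tau) * sigma


def true_fixed_effect(config: GeneratorConfig, dummy: str, tau: float) -> float:
    """Exact tau-quantile contrast of one dummy at reference levels.

    For the location-scale generator the contrast of switching a single dummy
    on, with everything else at reference, is

        beta_loc + Phi^{-1}(tau) * sigma_ref * (exp(gamma) - 1),

    with ``sigma_ref = exp(gamma0)``.  When the dummy has no scale effect this
    reduces to ``beta_loc``; with several scale dummies switched on jointly the
    quantile surface is no longer additive, which is why recovery experiments
    place a scale effect on a single covariate.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    beta = config.fixed_effect_location.get(dummy, 0.0)
    gamma = config.fixed_effect_logscale.get(dummy, 0.0)
    sigma_ref = float(np.exp(config.intercept_logscale))
    return beta + norm.ppf(tau) * sigma_ref * (np.exp(gamma) - 1.0)


def _latent_truth(config: GeneratorConfig, graph: RegionGraph,
                  rng: np.random.Generator) -> dict[str, dict[Any, float]]:
    region = dict.fromkeys(graph.nodes, 0.0)
    if config.spatial_precision is not None:
        icar = build_latent_precision(LatentSpec("ICAR", graph=graph))
        u = sample_constrained_gmrf(icar, config.spatial_precision, rng)
        region = dict(zip(graph.nodes, map(float, u)))
    steps = rng.standard_normal(len(config.years)) * config.temporal_sd
    v = np.cumsum(steps)
    v -= v.mean()
    return {"region": region, "year": dict(zip(config.years, map(float, v)))}


def generate_dataset(config: GeneratorConfig, graph: RegionGraph) -> AnalysisDataset:
    """Simulate one fully reproducible child-level table.

    The wealth quintile is set missing for every record of the years listed in
    ``config.wealth_missing_years`` (by default the year 2000, as in the
    emulated surveys).
    """
    rng = np.random.default_rng(config.seed)
    latent = _latent_truth(config, graph, rng)
    frames = []
    for year in config.years:
        n = config.n_per_year
        rec: dict[str, Any] = {"year": np.full(n, year, dtype=int)}
        for name, p in config.covariate_prevalences.items():
            if isinstance(p, Mapping):
                levels = list(p)
                rec[name] = rng.choice(levels, size=n, p=[p[lv] for lv in levels])
            else:
                rec[name] = rng.random(n) < p
        rec["child_age_months"] = rng.integers(0, 60, size=n)
        firstborn = rng.random(n) < config.firstborn_prob
        pbi = 9 + np.minimum(np.round(rng.gamma(3.0, 12.0, size=n)), 171).astype(int)
        rec["preceding_birth_interval_months"] = pd.array(
            np.where(firstborn, -1, pbi), dtype="Int64")
        rec["region_id"] = rng.choice(list(graph.nodes), size=n)
        df = pd.DataFrame(rec)
        df.loc[firstborn, "preceding_birth_interval_months"] = pd.NA
        if "wealth" in df.columns and year in config.wealth_missing_years:
            df["wealth"] = pd.Series([pd.NA] * n, dtype=object)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    for name, p in config.covariate_prevalences.items():
        if isinstance(p, Mapping):  # canonical level order, first = reference
            df[name] = pd.Categorical(df[name], categories=list(p))
    loc, lsc = _predictors(config, df)
    loc = loc + df["region_id"].map(latent["region"]).to_numpy(dtype=float)
    loc = loc + df["year"].map(latent["year"]).to_numpy(dtype=float)
    df.insert(0, "bmiaz", loc + np.exp(lsc) * rng.standard_normal(len(df)))
    truth = {
        "config": config,
        "latent_effects": latent,
        "dummy_labels": _dummy_labels(config),
    }
    return AnalysisDataset(df, truth)


def write_dataset(data: AnalysisDataset, path: str | Path) -> Path:
    """Write the table as UTF-8 comma-separated text with a header row.

    Column dictionary: ``bmiaz`` BMI-for-age z-score (float, never missing);
    ``year`` survey year; binary covariates as ``True``/``False``; factor
    covariates as level labels; ``child_age_months`` int 0-59;
    ``preceding_birth_interval_months`` int >= 9, empty field = first-born;
    ``region_id`` a node label of the adjacency graph.  Missing values are
    written as empty fields and floats with 17 significant digits, so the
    file round-trips losslessly through :func:`read_dataset`.
    """
    path = Path(path)
    data.df.to_csv(path, index=False, na_rep="", float_format="%.17g")
    return path


def read_dataset(path: str | Path, graph: RegionGraph | None = None) -> AnalysisDataset:
    """Read a CSV written by :func:`write_dataset` (lossless round-trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "preceding_birth_interval_months" in df.columns:
        df["preceding_birth_interval_months"] = df[
            "preceding_birth_interval_months"].astype("Int64")
    for col in df.columns:
        if df[col].dtype == object:
            vals = df[col].dropna().unique()
            if set(vals) <= {"True", "False"}:
                df[col] = df[col].map({"True": True, "False": False})
    if graph is not None:
        unknown = set(df["region_id"].dropna().unique()) - set(graph.nodes)
        if unknown:
            raise ValueError(f"region labels not in graph: {sorted(unknown)}")
    return AnalysisDataset(df)
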