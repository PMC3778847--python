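"""Synthetic small-area studies with known ground truth.

Generates a lattice of census-tract-like areas carrying (i) a latent
deprivation field with tunable spatial smoothness, (ii) a battery of
correlated socioeconomic indicators loading on that field, and (iii)
Poisson death counts from the ecological model

    O_i ~ Poisson(Pop_i * exp(alpha + sum_k beta_k 1[Q_i = k+1]
                               + beta5 * age4564_i + beta6 * age65_i
                               + upsilon_i + S_i))

with iid heterogeneity upsilon_i ~ N(0, sigma_v^2) and a spatially
structured ICAR effect S scaled to typical marginal SD sigma_S and
constrained to sum to zero.  Every stage is driven by named sub-streams of
a single seed so studies are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AdjacencyGraph, ICARStructure, icar_structure, make_lattice, \
    read_adjacency, write_adjacency
from .index import IndicatorSpec, assign_quintiles

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_indicators",
    "simulate_mortality",
    "make_study",
    "make_confounded_age_scenario",
    "morans_i",
    "write_study",
    "read_study",
]

_COUNT_GUARD = 1e7  # expected deaths per tract above this is a config error


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic small-area study.

    Defaults emulate a metropolitan census-tract study at desk scale: a
    30x30 lattice (900 tracts), 16 indicators loading on one latent
    deprivation gradient, tract populations uniform in [500, 2000]
    (Spanish census tracts average ~1200 inhabitants), a baseline death
    rate of 1% per tract-period, modest quintile gradients and random
    effect spreads of the size seen in urban mortality mapping.
    """

    rows: int = 30
    cols: int = 30
    n_indicators: int = 16
    indicator_loading: float | np.ndarray = 1.0
    indicator_noise_sd: float = 0.3
    spatial_range: float = 0.7  # weight of the ICAR component of the latent field
    baseline_rate: float = 0.01
    true_log_rr: tuple = (0.1, 0.2, 0.2, 0.3)  # quintiles 2..5 vs 1
    beta_age4564: float = 0.5
    beta_age65: float = 1.5
    sigma_S: float = 0.3
    sigma_v: float = 0.5
    pop_min: int = 500
    pop_max: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.rows * self.cols < 25:
            raise ValueError("lattice must have at least 25 tracts")
        if not (0 < self.baseline_rate < 1):
            raise ValueError("baseline_rate must lie in (0, 1)")
        if len(tuple(self.true_log_rr)) != 4:
            raise ValueError("true_log_rr needs exactly 4 entries (Q2..Q5 vs Q1)")
        if self.sigma_S < 0 or self.sigma_v < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not (0 <= self.spatial_range <= 1):
            raise ValueError("spatial_range is a mixing weight in [0, 1]")
        if self.pop_min <= 0 or self.pop_max < self.pop_min:
            raise ValueError("need 0 < pop_min <= pop_max")
        if self.indicator_noise_sd < 0:
            raise ValueError("indicator_noise_sd must be nonnegative")

    def loadings(self) -> np.ndarray:
        lo = np.asarray(self.indicator_loading, dtype=float)
        if lo.ndim == 0:
            lo = np.full(self.n_indicators, float(lo))
        if lo.shape != (self.n_indicators,):
            raise ValueError("indicator_loading must be scalar or one per indicator")
        return lo

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_log_rr"] = list(np.asarray(self.true_log_rr, dtype=float))
        d["indicator_loading"] = np.asarray(self.loadings()).tolist()
        return d


@dataclass
class SyntheticStudy:
    """A complete generated study: graph + indicators + outcomes + truth."""

    graph: AdjacencyGraph
    indicators: pd.DataFrame  # tract_id index, one column per indicator
    specs: list[IndicatorSpec]
    outcomes: pd.DataFrame  # tract_id, pop, deaths, age4564, age65, quintile
    truth: dict = field(repr=False)

    @property
    def n(self) -> int:
        return self.graph.n


def _streams(seed: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def _latent_field(structure: ICARStructure, spatial_range: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latent deprivation field.

    A convex mixture (on the variance scale) of a unit-marginal-SD ICAR
    draw and iid noise: weight ``spatial_range`` on the spatial part.
    ``spatial_range=0`` gives a spatially unstructured field (Moran's I
    ~ 0); ``1`` a fully ICAR-smooth field.
    """
    w = float(spatial_range)
    z = rng.standard_normal(structure.n)
    if w == 0:
        return z
    s = structure.draw(rng, unit_marginal=True)
    return np.sqrt(w) * s + np.sqrt(1.0 - w) * z


def simulate_indicators(graph: AdjacencyGraph, config: SimulationConfig,
                        latent: np.ndarray | None = None,
                        rng: np.random.Generator | None = None):
    """Indicator battery loading on the latent deprivation field.

    Each column j is ``loading_j * latent + noise`` mapped affinely to a
    percentage-like scale (mean 30, SD 12), with polarity metadata set to
    adverse for every generated column (higher = more deprived).  Returns
    ``(indicators DataFrame, specs, latent)``.
    """
    if rng is None:
        rng = _streams(config.seed, ["field", "noise"])["noise"]
    if latent is None:
        structure = icar_structure(graph)
        latent = _latent_field(structure, config.spatial_range,
                               _streams(config.seed, ["field"])["field"])
    lo = config.loadings()
    n = graph.n
    cols = {}
    specs = []
    for j in range(config.n_indicators):
        for _ in range(10):
            raw = lo[j] * latent + config.indicator_noise_sd * rng.standard_normal(n)
            if raw.std() > 0:
                break
        else:
            raise RuntimeError(f"indicator {j} degenerate after 10 attempts")
        name = f"ind{j:02d}"
        cols[name] = 30.0 + 12.0 * raw
        specs.append(IndicatorSpec(name=name, polarity="adverse", units="%"))
    df = pd.DataFrame(cols, index=pd.Index(graph.tract_ids, name="tract_id"))
    return df, specs, latent


def simulate_mortality(graph: AdjacencyGraph, quintile: np.ndarray,
                       age4564: np.ndarray, age65: np.ndarray,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       structure: ICARStructure | None = None):
    """Draw per-tract populations, random effects and Poisson deaths.

    Returns ``(outcomes DataFrame, truth dict)`` where truth records the
    drawn upsilon, S and every generative parameter.
    """
    quintile = np.asarray(quintile, dtype=int)
    if quintile.min() < 1 or quintile.max() > 5:
        raise ValueError("quintile labels must lie in {1..5}")
    age4564 = np.asarray(age4564, dtype=float)
    age65 = np.asarray(age65, dtype=float)
    if ((age4564 < 0) | (age4564 > 1) | (age65 < 0) | (age65 > 1)).any():
        raise ValueError("age proportions must lie in [0, 1]")
    if rng is None:
        rng = _streams(config.seed, ["counts"])["counts"]
    if structure is None:
        structure = icar_structure(graph)
    n = graph.n
    pop = rng.integers(config.pop_min, config.pop_max + 1, size=n)
    upsilon = config.sigma_v * rng.standard_normal(n)
    if config.sigma_S > 0:
        S = config.sigma_S * structure.draw(rng, unit_marginal=True)
    else:
        S = np.zeros(n)
    beta = np.asarray(config.true_log_rr, dtype=float)
    alpha = np.log(config.baseline_rate)
    qeff = np.where(quintile >= 2, beta[np.clip(quintile - 2, 0, 3)], 0.0)
    eta = (alpha + qeff + config.beta_age4564 * age4564
           + config.beta_age65 * age65 + upsilon + S)
    mu = pop * np.exp(eta)
    if (mu > _COUNT_GUARD).any():
        raise ValueError("expected count exceeds overflow guard; check config")
    deaths = rng.poisson(mu)
    outcomes = pd.DataFrame(
        {
            "tract_id": graph.tract_ids,
            "pop": pop,
            "deaths": deaths,
            "age4564": age4564,
            "age65": age65,
            "quintile": quintile,
        }
    )
    truth = {
        "alpha": float(alpha),
        "true_log_rr": beta.tolist(),
        "beta_age4564": config.beta_age4564,
        "beta_age65": config.beta_age65,
        "sigma_S": config.sigma_S,
        "sigma_v": config.sigma_v,
        "upsilon": upsilon.tolist(),
        "S": S.tolist(),
        "eta": eta.tolist(),
    }
    return outcomes, truth


def _age_structure(n: int, rng: np.random.Generator,
                   latent_for_corr: np.ndarray | None = None,
                   target_r: float = 0.0):
    """Tract age-structure proportions.

    Baselines mimic an urban Spanish age pyramid (about 25% aged 45-64,
    18% aged 65+).  With ``target_r`` nonzero, the 65+ share is built so
    its Pearson correlation with ``latent_for_corr`` is ``target_r`` in
    expectation.
    """
    a4564 = np.clip(0.25 + 0.04 * rng.standard_normal(n), 0.02, 0.6)
    z = rng.standard_normal(n)
    if latent_for_corr is not None and target_r != 0.0:
        if abs(target_r) > 1:
            raise ValueError("target correlation must lie in [-1, 1]")
        q = np.asarray(latent_for_corr, dtype=float)
        qs = (q - q.mean()) / q.std()
        mix = target_r * qs + np.sqrt(1 - target_r**2) * z
    else:
        mix = z
    a65 = np.clip(0.18 + 0.05 * mix, 0.01, 0.6)
    return a4564, a65


def make_study(config: SimulationConfig, age_quintile_r: float = 0.0) -> SyntheticStudy:
    """Generate a full study: lattice, latent field, indicators, outcomes.

    Quintile labels are taken from the rank of the latent deprivation
    field itself (equal counts, ties broken by tract order), so the
    generative quintile effects refer to true deprivation, not to the
    reconstructed index.
    """
    graph = make_lattice(config.rows, config.cols)
    structure = icar_structure(graph)
    rngs = _streams(config.seed, ["field", "noise", "age", "counts"])
    latent = _latent_field(structure, config.spatial_range, rngs["field"])
    indicators, specs, _ = simulate_indicators(
        graph, config, latent=latent, rng=rngs["noise"]
    )
    quintile = assign_quintiles(latent).labels
    a4564, a65 = _age_structure(
        graph.n, rngs["age"],
        latent_for_corr=quintile.astype(float),
        target_r=age_quintile_r,
    )
    outcomes, truth = simulate_mortality(
        graph, quintile, a4564, a65, config, rng=rngs["counts"],
        structure=structure,
    )
    truth["latent"] = latent.tolist()
    truth["config"] = config.to_dict()
    truth["age_quintile_r"] = age_quintile_r
    return SyntheticStudy(graph=graph, indicators=indicators, specs=specs,
                          outcomes=outcomes, truth=truth)


def make_confounded_age_scenario(config: SimulationConfig,
                                 target_r: float = 0.6) -> SyntheticStudy:
    """Study in which tract age structure tracks deprivation.

    The 65+ population share is positively correlated (Pearson r ~
    ``target_r``) with the deprivation quintile rank, so a model that
    adjusts the response but not the predictor for age is biased for the
    deprivation effect.
    """
    if abs(target_r) > 1:
        raise ValueError("unattainable correlation target")
    return make_study(config, age_quintile_r=target_r)


def morans_i(graph: AdjacencyGraph, x: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of x over binary weights."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    W = graph.adjacency_matrix()
    num = float(xc @ (W @ xc))
    den = float(xc @ xc)
    s0 = W.sum()
    return graph.n / s0 * num / den


def study_loglik_at_truth(study: SyntheticStudy) -> float:
    """Generator-side Poisson log-density of the drawn counts at truth.

    Cross-check oracle for the model module's likelihood evaluator.
    """
    from scipy.special import gammaln

    eta = np.asarray(study.truth["eta"])
    O = study.outcomes["deaths"].to_numpy()
    pop = study.outcomes["pop"].to_numpy()
    mu = pop * np.exp(eta)
    return float(np.sum(O * np.log(mu) - mu - gammaln(O + 1)))


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write tracts.csv, indicators.csv, adjacency.gal and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracts": outdir / "tracts.csv",
        "indicators": outdir / "indicators.csv",
        "adjacency": outdir / "adjacency.gal",
        "truth": outdir / "truth.json",
    }
    study.outcomes.to_csv(paths["tracts"], index=False)
    study.indicators.to_csv(paths["indicators"])
    write_adjacency(study.graph, paths["adjacency"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_study(directory) -> SyntheticStudy:
    """Read a study directory written by :func:`write_study`."""
    directory = Path(directory)
    outcomes = pd.read_csv(directory / "tracts.csv")
    indicators = pd.read_csv(directory / "indicators.csv", index_col="tract_id")
    graph = read_adjacency(directory / "adjacency.gal")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    specs = [IndicatorSpec(name=c) for c in indicators.columns]
    return SyntheticStudy(graph=graph, indicators=indicators, specs=specs,
                          outcomes=outcomes, truth=truth)
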