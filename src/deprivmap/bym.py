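"""Modified Besag-York-Mollié ecological Poisson regression.

The model for per-tract death counts is

    O_i ~ Poisson(Pop_i * exp(eta_i))
    eta_i = alpha + sum_{k=1}^{4} beta_k 1[Q_i = k+1]
            + beta5 * age4564_i + beta6 * age65_i + upsilon_i + S_i

i.e. the *crude rate* is modelled with the population as offset and the
tract age structure entering as covariates (rather than age-standardizing
the response), which avoids the mutual-standardization bias of ecological
regressions.  The deprivation index enters as standardized equal-count
quintiles (Q1 = least deprived is the reference), both to capture
non-linearity and to blunt concurvity between a smooth deprivation field
and the spatial random effect.  ``upsilon`` is iid Gaussian heterogeneity
and ``S`` an intrinsic CAR (ICAR) effect on the tract adjacency graph,
constrained to sum to zero per graph component.

Two inference engines are provided: a Metropolis-within-Gibbs MCMC
reference sampler and an INLA-style engine that combines Gaussian
(Laplace) approximations of the latent field with numerical integration
of the two hyperparameters over a central-composite design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graph import AdjacencyGraph, icar_structure

__all__ = [
    "ModelSpec",
    "Priors",
    "Design",
    "PosteriorResult",
    "build_design",
    "loglik",
    "fit_mcmc",
    "fit_laplace",
    "posterior_rr",
    "BYMPoissonRegression",
]


class DesignError(ValueError):
    """The requested design cannot be built from the data (rank deficiency,
    missing columns, nonpositive populations)."""


class FitError(RuntimeError):
    """Inference failed (non-convergence, non-finite posterior)."""


@dataclass(frozen=True)
class ModelSpec:
    """What enters the linear predictor and what serves as offset.

    deprivation : 'quintile' | 'continuous' | None
        Quintile dummies (Q2..Q5 vs Q1, the model's default), a single
        continuous deprivation column, or no deprivation term.
    include_age : bool
        Include the age-structure covariates age4564 and age65.
    offset_mode : 'population' | 'expected_counts'
        Population offset (crude-rate model) or an expected-count offset
        taken from an ``expected`` column (the response-standardized
        variant used as a comparison arm in the experiments).
    covariate_standardization : bool
        z-score continuous covariates; the transform is recorded so
        coefficients can be mapped back to the per-unit scale.
    """

    deprivation: str | None = "quintile"
    include_age: bool = True
    offset_mode: str = "population"
    covariate_standardization: bool = True

    def __post_init__(self):
        if self.deprivation not in ("quintile", "continuous", None):
            raise ValueError("deprivation must be 'quintile', 'continuous' or None")
        if self.offset_mode not in ("population", "expected_counts"):
            raise ValueError("offset_mode must be 'population' or 'expected_counts'")


@dataclass(frozen=True)
class Priors:
    """Prior specification; the model is otherwise improper.

    Fixed effects get independent N(0, beta_sd^2); the two precisions get
    Gamma(shape, rate) priors.  Defaults are the vague choices customary
    in disease mapping: variance 1000 on coefficients and Gamma(1, 5e-4)
    on each precision.
    """

    beta_sd: float = np.sqrt(1000.0)
    logprec_het: tuple = (1.0, 5e-4)
    logprec_spat: tuple = (1.0, 5e-4)

    def __post_init__(self):
        if self.beta_sd <= 0:
            raise ValueError("beta_sd must be positive")
        for nm in ("logprec_het", "logprec_spat"):
            a, b = getattr(self, nm)
            if a <= 0 or b <= 0:
                raise ValueError(f"{nm} Gamma hyperparameters must be positive")


@dataclass
class Design:
    """Fixed-effect design matrix, offset and response, ready for fitting."""

    X: np.ndarray  # n x p, first column is the intercept
    names: list[str]
    O: np.ndarray  # observed deaths
    pop: np.ndarray
    log_offset: np.ndarray
    transform: dict  # name -> (mean, sd) for standardized columns
    weight: np.ndarray  # 0/1 likelihood inclusion per tract (masking)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


_REQUIRED = ("deaths", "pop")


def build_design(outcomes: pd.DataFrame, spec: ModelSpec = ModelSpec(),
                 mask: np.ndarray | None = None) -> Design:
    """Assemble the fixed-effect design from the tract outcome table.

    Expects columns ``deaths``, ``pop`` and, depending on the spec,
    ``quintile`` (labels 1..5, all levels present), ``deprivation``
    (continuous), ``age4564``/``age65`` and ``expected``.  ``mask`` marks
    tracts whose likelihood contribution is dropped (used by the exact
    leave-one-out oracle); their rows stay in the design.
    """
    for col in _REQUIRED:
        if col not in outcomes.columns:
            raise DesignError(f"outcomes table lacks required column {col!r}")
    n = len(outcomes)
    O = outcomes["deaths"].to_numpy(dtype=float)
    pop = outcomes["pop"].to_numpy(dtype=float)
    if (O < 0).any() or not np.isfinite(O).all():
        raise DesignError("deaths must be finite and nonnegative")
    if (pop <= 0).any():
        raise DesignError("tracts with nonpositive population are not fittable")

    cols = [np.ones(n)]
    names = ["alpha"]
    transform: dict = {}

    if spec.deprivation == "quintile":
        if "quintile" not in outcomes.columns:
            raise DesignError("spec requests quintiles but none in table")
        q = outcomes["quintile"].to_numpy(dtype=int)
        for level in range(1, 6):
            if not (q == level).any():
                raise DesignError(
                    f"quintile level {level} absent: dummy block is rank-deficient"
                )
        for level in range(2, 6):
            cols.append((q == level).astype(float))
            names.append(f"beta_q{level}")
    elif spec.deprivation == "continuous":
        if "deprivation" not in outcomes.columns:
            raise DesignError("spec requests continuous deprivation column")
        x = outcomes["deprivation"].to_numpy(dtype=float)
        if spec.covariate_standardization:
            m, s = x.mean(), x.std(ddof=0)
            if s <= 0:
                raise DesignError("deprivation column has zero variance")
            transform["beta_depriv"] = (float(m), float(s))
            x = (x - m) / s
        cols.append(x)
        names.append("beta_depriv")

    if spec.include_age:
        for col, nm in (("age4564", "beta_age4564"), ("age65", "beta_age65")):
            if col not in outcomes.columns:
                raise DesignError(f"spec requests age covariates but {col!r} missing")
            x = outcomes[col].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise DesignError(f"missing values in covariate {col!r}")
            if spec.covariate_standardization:
                m, s = x.mean(), x.std(ddof=0)
                if s <= 0:
                    raise DesignError(f"covariate {col!r} has zero variance")
                transform[nm] = (float(m), float(s))
                x = (x - m) / s
            cols.append(x)
            names.append(nm)

    if spec.offset_mode == "expected_counts":
        if "expected" not in outcomes.columns:
            raise DesignError("offset_mode='expected_counts' needs an 'expected' column")
        E = outcomes["expected"].to_numpy(dtype=float)
        if (E <= 0).any():
            raise DesignError("expected counts must be positive")
        log_offset = np.log(E)
    else:
        log_offset = np.log(pop)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("fixed-effect design is rank-deficient")
    weight = np.ones(n) if mask is None else np.where(np.asarray(mask), 0.0, 1.0)
    return Design(X=X, names=names, O=O, pop=pop, log_offset=log_offset,
                  transform=transform, weight=weight)


def unstandardize_coefficients(mean: np.ndarray, design: Design) -> dict:
    """Map posterior means of standardized coefficients back to the
    per-unit covariate scale (intercept absorbs the recentring)."""
    out = dict(zip(design.names, np.asarray(mean, dtype=float)))
    shift = 0.0
    for nm, (m, s) in design.transform.items():
        b = out[nm]
        out[nm] = b / s
        shift += b * m / s
    out["alpha"] = out["alpha"] - shift
    return out


def loglik(eta: np.ndarray, O: np.ndarray, pop: np.ndarray,
           weight: np.ndarray | None = None) -> float:
    """Poisson log-likelihood sum_i O_i eta*_i - Pop_i e^{eta_i} - log O_i!

    ``eta`` is the full log relative-risk (so the mean is ``pop * exp(eta)``).
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    mu = pop * np.exp(eta)
    terms = O * (eta + np.log(pop)) - mu - gammaln(O + 1)
    if weight is not None:
        terms = terms * weight
    return float(terms.sum())


@dataclass
class PosteriorResult:
    """Posterior summaries of a fitted BYM model.

    ``fixed`` rows follow design order (alpha, beta_q2..beta_q5, age
    terms) with mean/sd/percentiles and, for beta rows, the relative-risk
    transform.  ``hyper`` summarizes sigma_S (marginal scale) and
    sigma_v.  ``latent`` holds per-tract summaries of upsilon and S.
    """

    engine: str
    fixed: pd.DataFrame
    hyper: pd.DataFrame
    latent: pd.DataFrame
    design: Design = field(repr=False)
    meta: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict, repr=False)  # mcmc only
    mixture: dict = field(default_factory=dict, repr=False)  # laplace only
    accum: dict = field(default_factory=dict, repr=False)  # mcmc streaming stats

    def coef(self) -> np.ndarray:
        return self.fixed["mean"].to_numpy()


def posterior_rr(result: PosteriorResult) -> pd.DataFrame:
    """Relative-risk table in the reporting layout of small-area studies.

    RR rows are exp of the beta posterior quantiles (Q2..Q5 vs Q1 for the
    quintile model); age coefficients are reported on their own (log)
    scale; sigma_S and sigma_v posterior mean (SD) are appended.
    """
    rows = []
    for name, r in result.fixed.iterrows():
        if str(name).startswith("beta_q") or str(name) == "beta_depriv":
            rows.append({
                "parameter": f"RR {name[5:].upper()}" if str(name).startswith("beta_q")
                else "RR deprivation",
                "estimate": float(np.exp(r["mean"])),
                "lo95": float(np.exp(r["q2.5"])),
                "hi95": float(np.exp(r["q97.5"])),
            })
        elif str(name).startswith("beta_age"):
            rows.append({
                "parameter": name,
                "estimate": float(r["mean"]),
                "lo95": float(r["q2.5"]),
                "hi95": float(r["q97.5"]),
            })
    for name, r in result.hyper.iterrows():
        rows.append({
            "parameter": f"sigma_{'S' if name == 'sigma_S' else 'v'} (mean, SD)",
            "estimate": float(r["mean"]),
            "lo95": float(r["mean"] - r["sd"]),
            "hi95": float(r["mean"] + r["sd"]),
        })
    return pd.DataFrame(rows)


def fit_mcmc(spec: ModelSpec, outcomes: pd.DataFrame, graph: AdjacencyGraph,
             priors: Priors = Priors(), n_iter: int = 20000, n_burn: int = 5000,
             seed: int = 0, mask: np.ndarray | None = None,
             thin_store: int | None = None) -> PosteriorResult:
    """Metropolis-within-Gibbs reference sampler.  See ``_mcmc``."""
    from ._mcmc import run_mcmc

    design = build_design(outcomes, spec, mask=mask)
    structure = icar_structure(graph)
    return run_mcmc(design, structure, priors, n_iter=n_iter, n_burn=n_burn,
                    seed=seed, thin_store=thin_store)


def fit_laplace(spec: ModelSpec, outcomes: pd.DataFrame, graph: AdjacencyGraph,
                priors: Priors = Priors(), grid_strategy: str = "ccd",
                latent_summaries: bool = True,
                mask: np.ndarray | None = None) -> PosteriorResult:
    """Gaussian-approximation engine with CCD hyperparameter integration.

    ``grid_strategy`` is ``'ccd'`` (mode + 8 star/corner points, the
    default), ``'mode'`` (single support point) or an explicit list of
    ``(tau_v, tau_S)`` support points.  ``latent_summaries=False`` skips
    the dense covariance pass (fixed effects and hyperparameters only),
    which is much faster for experiment sweeps.
    """
    from ._laplace import run_laplace

    design = build_design(outcomes, spec, mask=mask)
    structure = icar_structure(graph)
    return run_laplace(design, structure, priors, grid_strategy=grid_strategy,
                       latent_summaries=latent_summaries)


class BYMPoissonRegression:
    """scikit-learn-style estimator for the BYM ecological regression.

    Parameters mirror :class:`ModelSpec` plus engine controls.  ``fit``
    takes the tract outcome table and the adjacency graph; fitted
    attributes carry the posterior summaries.

    Examples
    --------
    >>> model = BYMPoissonRegression(engine="laplace")
    >>> model.fit(outcomes, graph)                        # doctest: +SKIP
    >>> model.rr_                                         # doctest: +SKIP
    """

    def __init__(self, engine: str = "laplace", deprivation: str | None = "quintile",
                 include_age: bool = True, offset_mode: str = "population",
                 covariate_standardization: bool = True, priors: Priors = Priors(),
                 n_iter: int = 20000, n_burn: int = 5000, seed: int = 0,
                 grid_strategy: str = "ccd", latent_summaries: bool = True):
        self.engine = engine
        self.deprivation = deprivation
        self.include_age = include_age
        self.offset_mode = offset_mode
        self.covariate_standardization = covariate_standardization
        self.priors = priors
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.seed = seed
        self.grid_strategy = grid_strategy
        self.latent_summaries = latent_summaries

    _param_names = ("engine", "deprivation", "include_age", "offset_mode",
                    "covariate_standardization", "priors", "n_iter", "n_burn",
                    "seed", "grid_strategy", "latent_summaries")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def spec(self) -> ModelSpec:
        return ModelSpec(
            deprivation=self.deprivation,
            include_age=self.include_age,
            offset_mode=self.offset_mode,
            covariate_standardization=self.covariate_standardization,
        )

    def fit(self, X: pd.DataFrame, y=None, graph: AdjacencyGraph = None,
            mask: np.ndarray | None = None):
        """Fit to the outcome table ``X`` on adjacency ``graph``.

        ``X`` must contain deaths/pop plus the covariates the spec needs;
        ``y`` is accepted for pipeline compatibility and, when given,
        overrides the ``deaths`` column.
        """
        if graph is None:
            raise ValueError("an AdjacencyGraph is required")
        if y is not None:
            X = X.copy()
            X["deaths"] = np.asarray(y)
        if self.engine == "mcmc":
            res = fit_mcmc(self.spec(), X, graph, priors=self.priors,
                           n_iter=self.n_iter, n_burn=self.n_burn,
                           seed=self.seed, mask=mask)
        elif self.engine == "laplace":
            res = fit_laplace(self.spec(), X, graph, priors=self.priors,
                              grid_strategy=self.grid_strategy,
                              latent_summaries=self.latent_summaries, mask=mask)
        else:
            raise ValueError(f"unknown engine {self.engine!r}")
        self.result_ = res
        self.fixed_ = res.fixed
        self.hyper_ = res.hyper
        self.latent_ = res.latent
        self.rr_ = posterior_rr(res)
        self.sigma_s_ = float(res.hyper.loc["sigma_S", "mean"])
        self.sigma_v_ = float(res.hyper.loc["sigma_v", "mean"])
        return self

    def predict(self, X: pd.DataFrame = None) -> np.ndarray:
        """Posterior-mean expected deaths for the fitted tracts."""
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")
        d = self.result_.design
        lin = d.X @ self.result_.coef() \
            + self.result_.latent["u_mean"].to_numpy() \
            + self.result_.latent["S_mean"].to_numpy()
        return np.exp(d.log_offset + lin)
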