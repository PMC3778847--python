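"""Pena DP2 composite deprivation index.

The DP2 distance aggregates standardized socioeconomic indicators into a
single tract-level deprivation score.  Each indicator contributes its
distance to a reference base weighted by ``1 - R^2`` of that indicator
regressed on the indicators already included, so duplicated information is
counted once while every variable stays in the index.  The ordering of
indicators is itself determined iteratively: indicators are ranked by
squared correlation with the current index and the index recomputed until
the ordering stabilises.

The construction satisfies the classical axioms of a good composite
indicator (monotony, unicity, invariance to affine rescaling of raw
inputs, homogeneity, transitivity, exhaustivity of duplicates, existence
and additivity), several of which are exercised directly in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorSpec",
    "DP2Result",
    "QuintileAssignment",
    "DP2Index",
    "orient_and_standardize",
    "frechet_index",
    "dp2",
    "assign_quintiles",
]

ADVERSE = "adverse"
FAVORABLE = "favorable"


class DegenerateIndicatorError(ValueError):
    """An indicator column has zero variance (or the index cannot be cut)."""


class ConvergenceError(RuntimeError):
    """DP2 ordering failed to reach a fixpoint within ``max_iter``."""

    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class IndicatorSpec:
    """Name, polarity and units of one partial indicator.

    ``polarity='adverse'`` means higher raw value indicates more
    deprivation (e.g. unemployment rate); ``'favorable'`` the opposite
    (e.g. university education) and the column is negated before
    standardization.
    """

    name: str
    polarity: str = ADVERSE
    units: str = "%"

    def __post_init__(self):
        if self.polarity not in (ADVERSE, FAVORABLE):
            raise ValueError(f"polarity must be adverse|favorable, got {self.polarity!r}")


@dataclass
class DP2Result:
    """Converged DP2 index together with its construction diagnostics."""

    index: np.ndarray
    ordering: np.ndarray  # permutation of column positions, first = anchor
    correction_factors: np.ndarray  # 1 - R^2, aligned with `ordering`
    n_iterations: int
    converged: bool
    frechet: np.ndarray
    ordering_trace: list = field(default_factory=list, repr=False)


@dataclass
class QuintileAssignment:
    """Equal-count quintile labels (1 = least deprived) and cutpoints."""

    labels: np.ndarray
    cutpoints: np.ndarray


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def orient_and_standardize(X, specs: list[IndicatorSpec] | None = None):
    """Orient favorable indicators and z-score every column.

    Favorable columns are negated so that higher always means more
    deprived, then each column is centred to mean 0 and scaled to SD 1.
    Missing values are rejected; a zero-variance column raises
    :class:`DegenerateIndicatorError` naming the column.

    Returns an object of the same kind as the input (DataFrame in,
    DataFrame out).
    """
    mat, names = _as_matrix(X)
    if np.isnan(mat).any():
        raise ValueError("indicator matrix contains missing values")
    if specs is not None:
        if len(specs) != mat.shape[1]:
            raise ValueError("one IndicatorSpec per column required")
        for j, spec in enumerate(specs):
            if spec.polarity == FAVORABLE:
                mat[:, j] = -mat[:, j]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s <= 0 or not np.isfinite(s):
            raise DegenerateIndicatorError(
                f"indicator {names[j]!r} has zero variance"
            )
    Z = (mat - mean) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


def frechet_index(Z, base: np.ndarray | None = None) -> np.ndarray:
    """Unit-weighted sum of distances to the base: DF_i = sum_j (z_ij - b_j).

    ``Z`` must already be oriented and standardized (column SDs are 1, so
    the per-indicator 1/sigma_j scaling is implicit).  With the default
    base — the column minimum — the index is nonnegative and zero only for
    a tract at the least-deprived observed value on every indicator.
    """
    mat, _ = _as_matrix(Z)
    base = mat.min(axis=0) if base is None else np.asarray(base, dtype=float)
    if base.shape != (mat.shape[1],):
        raise ValueError(
            f"base has length {base.shape}, expected ({mat.shape[1]},)"
        )
    if not np.all(np.isfinite(base)):
        raise ValueError("base must be finite")
    return (mat - base).sum(axis=1)


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of OLS with intercept of y on the columns of X.

    ``lstsq`` returns the minimum-norm solution on rank-deficient blocks,
    which leaves the fitted values (hence R^2) well defined.
    """
    if X.shape[1] == 0:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        return 1.0
    r2 = 1.0 - float((resid**2).sum()) / sst
    return min(1.0, max(0.0, r2))


def dp2(Z, base: np.ndarray | None = None, max_iter: int = 100,
        tol: float = 1e-10) -> DP2Result:
    """Iterate the DP2 aggregation to an ordering fixpoint.

    Starting from the Frechet index, each iteration (a) ranks indicators
    by decreasing squared correlation with the current index (ties broken
    by original column order), then (b) recomputes the index as
    ``sum_j d_ij * (1 - R^2_j)`` where ``R^2_j`` is the coefficient of
    determination of indicator j on the indicators preceding it in the
    ranking (0 for the first).  Stops when the ranking repeats or the
    index change falls below ``tol``.
    """
    mat, _ = _as_matrix(Z)
    n, p = mat.shape
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    b = mat.min(axis=0) if base is None else np.asarray(base, dtype=float)
    d = mat - b
    fre = d.sum(axis=1)

    index = fre.copy()
    prev_order = None
    trace: list[np.ndarray] = []
    converged = False
    order = np.arange(p)
    factors = np.ones(p)
    n_iterations = 0
    for it in range(1, max_iter + 1):
        sd_idx = index.std()
        if sd_idx <= 0:
            corr2 = np.zeros(p)  # degenerate index: fall back to column order
        else:
            zc = (index - index.mean()) / sd_idx
            corr2 = (mat.T @ zc / n) ** 2  # columns have mean 0, sd 1
        # rounding makes mathematically exact ties (e.g. two indicators
        # against their own sum) break by column order, not by fp noise
        new_order = np.argsort(-np.round(corr2, 12), kind="stable")
        if prev_order is not None and np.array_equal(new_order, prev_order):
            converged = True  # ordering fixpoint: recomputing changes nothing
            break
        order = new_order
        trace.append(order.copy())
        factors = np.empty(p)
        new_index = np.zeros(n)
        for pos, j in enumerate(order):
            r2 = _r_squared(mat[:, j], mat[:, order[:pos]])
            factors[pos] = 1.0 - r2
            new_index += d[:, j] * factors[pos]
        delta = float(np.max(np.abs(new_index - index)))
        index = new_index
        n_iterations = it
        if delta < tol:
            converged = True
            break
        prev_order = order
    if not converged:
        raise ConvergenceError(
            f"DP2 ordering did not stabilise in {max_iter} iterations", trace
        )
    return DP2Result(
        index=index,
        ordering=order,
        correction_factors=factors,
        n_iterations=n_iterations,
        converged=converged,
        frechet=fre,
        ordering_trace=trace,
    )


def assign_quintiles(index) -> QuintileAssignment:
    """Equal-count quintiles by rank; label 1 = least deprived.

    Ties are broken by position (tract order), so group sizes differ by at
    most one.  An index with no variation cannot be cut and raises
    :class:`DegenerateIndicatorError`.
    """
    index = np.asarray(index, dtype=float)
    n = len(index)
    if n < 5:
        raise ValueError("need at least 5 tracts to form quintiles")
    if not np.all(np.isfinite(index)):
        raise ValueError("index must be finite")
    if index.max() == index.min():
        raise DegenerateIndicatorError("index is constant; quintiles undefined")
    order = np.argsort(index, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = 1 + (np.arange(n) * 5) // n
    cutpoints = np.quantile(index, [0.2, 0.4, 0.6, 0.8])
    return QuintileAssignment(labels=labels, cutpoints=cutpoints)


class DP2Index:
    """Deprivation-index transformer in the scikit-learn style.

    ``fit`` learns the orientation/standardization parameters, the
    converged indicator ordering, the correction factors and the reference
    base on the training tracts; ``transform`` applies the frozen weights
    to (new) indicator data.  ``fit_transform(X)`` on the study table
    itself reproduces the classical DP2 index of that table.

    Parameters
    ----------
    specs : list of IndicatorSpec, optional
        Polarity metadata per column; default treats every column as
        adverse.
    base : 'min' or array
        Reference vector on the standardized scale; 'min' uses the
        column-wise minimum of the training data (least-deprived observed
        profile), making the index nonnegative.
    max_iter, tol : DP2 iteration controls.
    """

    def __init__(self, specs=None, base="min", max_iter=100, tol=1e-10):
        self.specs = specs
        self.base = base
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {"specs": self.specs, "base": self.base,
                "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        mat, names = _as_matrix(X)
        specs = self.specs
        if specs is None:
            specs = [IndicatorSpec(name) for name in names]
        signs = np.array(
            [-1.0 if s.polarity == FAVORABLE else 1.0 for s in specs]
        )
        oriented = mat * signs
        self.mean_ = oriented.mean(axis=0)
        self.scale_ = oriented.std(axis=0, ddof=0)
        for j, s in enumerate(self.scale_):
            if s <= 0 or not np.isfinite(s):
                raise DegenerateIndicatorError(
                    f"indicator {names[j]!r} has zero variance"
                )
        self.signs_ = signs
        Z = (oriented - self.mean_) / self.scale_
        if isinstance(self.base, str) and self.base == "min":
            base = Z.min(axis=0)
        else:
            base = np.asarray(self.base, dtype=float)
        self.base_ = base
        res = dp2(Z, base=base, max_iter=self.max_iter, tol=self.tol)
        self.result_ = res
        self.ordering_ = res.ordering
        self.correction_factors_ = res.correction_factors
        self.n_iterations_ = res.n_iterations
        # per-column weights in original column order
        w = np.empty(len(names))
        w[res.ordering] = res.correction_factors
        self.weights_ = w
        self.feature_names_in_ = names
        return self

    def transform(self, X):
        if not hasattr(self, "weights_"):
            raise RuntimeError("DP2Index is not fitted")
        mat, _ = _as_matrix(X)
        Z = (mat * self.signs_ - self.mean_) / self.scale_
        return (Z - self.base_) @ self.weights_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
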