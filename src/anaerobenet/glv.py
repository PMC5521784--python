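"""Signed interaction inference with a discrete-time gLV model and PLS1.

The generalized Lotka-Volterra model dx_i/dt = x_i (r_i + sum_j M_ij x_j)
is discretized by log-ratio gradient matching: for each transition between
consecutive samples,

    g_i(k) = [ln x_i(t_{k+1}) - ln x_i(t_k)] / (t_{k+1} - t_k)
           = r_i + sum_j M_ij x_j(t_k)          (exact under the
                                                 exponential-Euler step)

so each target taxon i yields a linear regression of its per-capita log
growth on the community state at the left endpoint of the transition. With
ten samples there are only nine transitions against up to 156 predictors,
which is why the regression is solved by partial least squares (NIPALS
PLS1) rather than ordinary least squares; the component count is chosen per
target by leave-one-out cross-validation unless fixed.

M_ij is the signed effect of taxon j on taxon i (per day per unit
abundance); the intercept estimates the intrinsic growth rate r_i (per
day). Self-effects M_ii are estimated but excluded from interaction counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .table import AbundanceTable

__all__ = [
    "GradientSet",
    "InteractionMatrix",
    "PLS1Regression",
    "GLVInteractionModel",
    "log_gradients",
    "pls_regress",
    "select_components",
    "infer_interactions",
]


@dataclass
class GradientSet:
    """Per-transition log-growth responses and left-endpoint predictors.

    ``responses[i, k]`` is g_i(k) for transition k (per day);
    ``predictors[k, j]`` is the (zero-replaced) abundance of taxon j at the
    transition's left endpoint.
    """

    taxa: list[str]
    responses: np.ndarray  # (n_taxa, t-1)
    predictors: np.ndarray  # (t-1, n_taxa)
    dt: np.ndarray  # (t-1,) day spacings


@dataclass
class InteractionMatrix:
    """Fitted gLV parameters for one condition.

    ``effects[i, j]`` is the effect of taxon j on taxon i; ``growth_rates``
    holds the per-target intercepts r_i. ``n_components_used`` records the
    PLS component count per target.
    """

    taxa: list[str]
    growth_rates: np.ndarray
    effects: np.ndarray
    n_components_used: np.ndarray = field(default=None)  # type: ignore[assignment]
    condition: str = ""

    def __post_init__(self) -> None:
        n = len(self.taxa)
        self.effects = np.asarray(self.effects, dtype=float)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.effects.shape != (n, n):
            raise ValueError(f"effects must be {n}x{n}")
        if not (np.all(np.isfinite(self.effects)) and np.all(np.isfinite(self.growth_rates))):
            raise ValueError("non-finite fitted parameters")
        if self.n_components_used is None:
            self.n_components_used = np.zeros(n, dtype=int)

    @property
    def n_interactions(self) -> int:
        """Off-diagonal (inter-taxon) effect count, N(N-1)."""
        n = len(self.taxa)
        return n * (n - 1)

    def subset(self, taxa: list[str]) -> "InteractionMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return InteractionMatrix(
            taxa=list(taxa),
            growth_rates=self.growth_rates[idx],
            effects=self.effects[np.ix_(idx, idx)],
            n_components_used=self.n_components_used[idx],
            condition=self.condition,
        )

    def edge_list(self) -> pd.DataFrame:
        """Long-format off-diagonal effects: source, target, strength."""
        rows = []
        for i, target in enumerate(self.taxa):
            for j, source in enumerate(self.taxa):
                if i != j:
                    rows.append((source, target, self.effects[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "strength"])


def _replace_zeros(values: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest nonzero value in the table."""
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("table has no positive abundances")
    out = values.copy()
    out[out == 0] = positive.min() / 2.0
    return out


def log_gradients(table: AbundanceTable) -> GradientSet:
    """Per-transition log-growth rates and left-endpoint predictors."""
    if table.n_times < 3:
        raise ValueError(f"need at least 3 time points, got {table.n_times}")
    x = _replace_zeros(table.values)
    dt = np.diff(np.asarray(table.days, dtype=float))
    logs = np.log(x)
    responses = (logs[:, 1:] - logs[:, :-1]) / dt
    predictors = x[:, :-1].T
    return GradientSet(taxa=list(table.taxa), responses=responses, predictors=predictors, dt=dt)


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_a: int) -> np.ndarray:
    """Coefficient path of NIPALS PLS1 on pre-scaled data.

    Returns an (max_a, p) array whose row a-1 holds the a-component
    coefficient vector (in the scaled predictor space). Extraction stops
    early when the response residual is numerically exhausted; remaining
    rows repeat the last valid solution, including the all-zero solution
    when no component can be extracted.
    """
    n, p = Xc.shape
    W = np.zeros((p, max_a))
    P = np.zeros((p, max_a))
    q = np.zeros(max_a)
    coefs = np.zeros((max_a, p))
    Xd, yd = Xc.copy(), yc.copy()
    extracted = 0
    for a in range(max_a):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # response residual exhausted
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-28:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = yd @ t / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
        extracted = a + 1
        k = extracted
        coefs[a] = W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])
    for a in range(extracted, max_a):
        coefs[a] = coefs[extracted - 1] if extracted else 0.0
    return coefs


def _center_scale(X: np.ndarray):
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    x_std = np.where(x_std > np.finfo(float).eps * 10, x_std, 1.0)
    return (X - x_mean) / x_std, x_mean, x_std


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Univariate-response partial least squares (NIPALS PLS1).

    Predictors are centered and scaled to unit variance (constant columns
    are centered but left unscaled); the response is centered only.
    Components are extracted by the classical deterministic NIPALS
    deflation, and coefficients are reported on the original predictor
    scale, so ``predict(X) = intercept_ + X @ coef_``.

    Component extraction stops early if the residual response is (numerically)
    zero, in which case remaining components contribute nothing.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Regression coefficients on the original scale.
    intercept_ : float
    n_components_ : int
        Number of components actually extracted (<= requested).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y) -> "PLS1Regression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} outside [1, {min(n - 1, p)}]"
            )

        Xc, x_mean, x_std = _center_scale(X)
        y_mean = y.mean()
        yc = y - y_mean

        path = _nipals_path(Xc, yc, self.n_components)
        coef_scaled = path[self.n_components - 1]
        # count components actually extracted (trailing rows repeat)
        a = self.n_components
        while a > 1 and np.array_equal(path[a - 1], path[a - 2]):
            a -= 1
        if a == 1 and not path[0].any():
            a = 0
        self.n_components_ = a
        self.coef_ = coef_scaled / x_std
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        self._x_mean = x_mean
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def pls_regress(X, y, n_components: int) -> tuple[np.ndarray, float]:
    """Fit PLS1 and return ``(coefficients, intercept)``."""
    m = PLS1Regression(n_components=n_components).fit(X, y)
    return m.coef_, m.intercept_


def select_components(X, y, max_components: int | None = None) -> int:
    """Choose the PLS component count by leave-one-out cross-validation.

    Returns the smallest count whose prediction-error sum of squares
    (PRESS) is within a relative 1e-8 of the minimum, which both breaks
    exact ties downward and avoids chasing float noise in flat PRESS
    profiles. With fewer than 3 samples LOO is undefined and 1 component is
    returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        return 1
    cap = min(n - 2, p)  # each LOO fold has n-1 rows, allowing n-2 components
    max_a = cap if max_components is None else min(max_components, cap)
    if max_a < 1:
        return 1

    press = np.zeros(max_a)
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, ytr = X[mask], y[mask]
        Xc, x_mean, x_std = _center_scale(Xtr)
        y_mean = ytr.mean()
        path = _nipals_path(Xc, ytr - y_mean, max_a)  # (max_a, p) scaled coefs
        coefs = path / x_std
        preds = y_mean + coefs @ (X[i] - x_mean)
        press += (preds - y[i]) ** 2
    best = press.min()
    tol = best + 1e-8 * (best + 1.0)
    return int(np.nonzero(press <= tol)[0][0]) + 1


class GLVInteractionModel(BaseEstimator):
    """Discrete-time gLV interaction inference, one PLS1 fit per target.

    Parameters
    ----------
    n_components : int or "auto"
        PLS component count per target. ``"auto"`` selects per target by
        leave-one-out PRESS.

    Attributes
    ----------
    taxa_ : list of str
    growth_rates_ : ndarray of shape (n_taxa,)
        Intercepts r_i (per day).
    effects_ : ndarray of shape (n_taxa, n_taxa)
        effects_[i, j] = effect of taxon j on taxon i.
    n_components_used_ : ndarray of int
    interaction_matrix_ : InteractionMatrix
    """

    def __init__(self, n_components: int | str = "auto"):
        self.n_components = n_components

    def fit(self, table: AbundanceTable, y=None) -> "GLVInteractionModel":
        grads = log_gradients(table)
        X = grads.predictors
        n_taxa = len(grads.taxa)
        effects = np.zeros((n_taxa, n_taxa))
        rates = np.zeros(n_taxa)
        used = np.zeros(n_taxa, dtype=int)
        for i in range(n_taxa):
            yi = grads.responses[i]
            if self.n_components == "auto":
                a = select_components(X, yi)
            else:
                a = int(self.n_components)
            coef, intercept = pls_regress(X, yi, a)
            effects[i] = coef
            rates[i] = intercept
            used[i] = a
        self.taxa_ = list(grads.taxa)
        self.growth_rates_ = rates
        self.effects_ = effects
        self.n_components_used_ = used
        self.interaction_matrix_ = InteractionMatrix(
            taxa=self.taxa_,
            growth_rates=rates,
            effects=effects,
            n_components_used=used,
            condition=table.condition,
        )
        return self

    def predict(self, table: AbundanceTable) -> np.ndarray:
        """Predicted per-capita log-growth rates g_i(k) for a table."""
        grads = log_gradients(table)
        return self.growth_rates_[:, None] + self.effects_ @ grads.predictors.T


def infer_interactions(
    table: AbundanceTable, n_components: int | str = "auto"
) -> InteractionMatrix:
    """Fit the gLV model to a table and return the interaction matrix."""
    return GLVInteractionModel(n_components=n_components).fit(table).interaction_matrix_
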