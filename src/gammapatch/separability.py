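"""Separability of a two-feature tuning matrix.

A joint tuning matrix M (one stimulus feature across rows, another across
columns) is separable when it is an outer product of two one-dimensional
tunings.  The degree of separability is quantified from the singular values
of M as

    si = lambda_1^2 / sum_i lambda_i^2,

which is 1 exactly when all singular values beyond the first vanish.  Three
regression models assess how much variance a separable description explains:

* rank-1 (SVD) model:    vec(M) ~ 1 + vec(u1 * lambda1 * v1^T)
* marginal product:      vec(M) ~ 1 + vec(F G^T)
* marginal sum:          vec(M) ~ F (+) G        (no intercept, same dof)

where F and G are the row/column marginals (sums across columns and rows).
Significance of si is assessed against matrices of i.i.d. normal entries
matched in mean and variance to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "TuningMatrix",
    "SeparabilityResult",
    "separability_index",
    "fit_rank1_model",
    "marginals",
    "fit_marginal_product",
    "fit_marginal_sum",
    "bootstrap_si_test",
    "r_squared",
    "analyze",
]


@dataclass
class TuningMatrix:
    """2-D grid of trial-averaged band responses over two feature axes."""

    values: np.ndarray
    axis_a: np.ndarray | None = None  # row feature levels
    axis_b: np.ndarray | None = None  # column feature levels
    name_a: str = ""
    name_b: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValidationError("tuning matrix needs >= 2 levels per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tuning matrix entries must be finite")
        for attr in ("axis_a", "axis_b"):
            ax = getattr(self, attr)
            if ax is not None:
                setattr(self, attr, np.asarray(ax, dtype=float))
        if self.axis_a is not None and len(self.axis_a) != self.values.shape[0]:
            raise ValidationError("axis_a length mismatch")
        if self.axis_b is not None and len(self.axis_b) != self.values.shape[1]:
            raise ValidationError("axis_b length mismatch")


@dataclass
class SeparabilityResult:
    si: float
    singular_values: np.ndarray
    u1: np.ndarray
    v1: np.ndarray
    r2_svd: float | None = None
    r2_marginal_product: float | None = None
    r2_marginal_sum: float | None = None
    p_bootstrap: float | None = None


def _as_matrix(M: TuningMatrix | np.ndarray) -> np.ndarray:
    if isinstance(M, TuningMatrix):
        return M.values
    return np.atleast_2d(np.asarray(M, dtype=float))


def separability_index(M: TuningMatrix | np.ndarray) -> SeparabilityResult:
    """Separability index and first singular pair of a tuning matrix.

    Raises :class:`DegenerateInputError` for the all-zero matrix, whose
    singular spectrum carries no information.
    """
    A = _as_matrix(M)
    if not np.any(A):
        raise DegenerateInputError("separability index undefined for a zero matrix")
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    si = float(s[0] ** 2 / np.sum(s**2))
    u1, v1 = u[:, 0], vt[0, :]
    # resolve SVD sign ambiguity: plotted marginals should not flip
    if u1.sum() < 0:
        u1, v1 = -u1, -v1
    return SeparabilityResult(si=si, singular_values=s, u1=u1, v1=v1)


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValidationError("observed and fitted must be equal-length, n >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("zero total variance: r^2 undefined")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """r^2 of the least-squares fit of y on the columns of X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return r_squared(y, X @ beta)


def fit_rank1_model(M: TuningMatrix | np.ndarray) -> float:
    """r^2 of the regression of vec(M) on [1, vec(u1 lambda1 v1^T)]."""
    A = _as_matrix(M)
    if np.ptp(A) == 0:
        raise DegenerateInputError("constant matrix: rank-1 fit degenerate")
    res = separability_index(A)
    rank1 = res.singular_values[0] * np.outer(res.u1, res.v1)
    y = A.ravel()
    X = np.column_stack([np.ones(y.size), rank1.ravel()])
    return _ols_r2(y, X)


def marginals(M: TuningMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row marginal F (sum across columns) and column marginal G (sum
    across rows)."""
    A = _as_matrix(M)
    return A.sum(axis=1), A.sum(axis=0)


def fit_marginal_product(M: TuningMatrix | np.ndarray) -> float:
    """r^2 of vec(M) regressed on [1, vec(F G^T)]."""
    A = _as_matrix(M)
    F, G = marginals(A)
    prod = np.outer(F, G)
    if np.ptp(prod) == 0:
        raise DegenerateInputError("constant marginal product: fit degenerate")
    y = A.ravel()
    X = np.column_stack([np.ones(y.size), prod.ravel()])
    return _ols_r2(y, X)


def fit_marginal_sum(M: TuningMatrix | np.ndarray) -> float:
    """r^2 of vec(M) regressed on the broadcast marginals F and G with no
    intercept (keeps the degrees of freedom equal to the product models)."""
    A = _as_matrix(M)
    F, G = marginals(A)
    nr, nc = A.shape
    Fb = np.repeat(F, nc)
    Gb = np.tile(G, nr)
    X = np.column_stack([Fb, Gb])
    if np.linalg.matrix_rank(X) < 2:
        raise DegenerateInputError("collinear marginals: sum fit degenerate")
    return _ols_r2(A.ravel(), X)


def bootstrap_si_test(
    M: TuningMatrix | np.ndarray,
    n_iter: int = 20,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Significance of the observed si against a matched-normal null.

    Generates ``n_iter`` matrices of M's shape with i.i.d. entries drawn from
    Normal(mean(M), var(M)), computes their separability indices, and returns
    the two-sided p value of a one-sample t test of those values against the
    observed si.
    """
    A = _as_matrix(M)
    if n_iter < 2:
        raise ValidationError("n_iter must be >= 2")
    sd = float(A.std())
    if sd == 0:
        raise DegenerateInputError("zero-variance matrix: bootstrap undefined")
    rng = np.random.default_rng(seed)
    observed = separability_index(A).si
    boot = np.empty(n_iter)
    for i in range(n_iter):
        null = rng.normal(A.mean(), sd, size=A.shape)
        s = np.linalg.svd(null, compute_uv=False)
        boot[i] = s[0] ** 2 / np.sum(s**2)
    return float(stats.ttest_1samp(boot, popmean=observed).pvalue)


def analyze(
    M: TuningMatrix | np.ndarray,
    n_iter: int = 20,
    seed: int | np.random.Generator | None = None,
) -> SeparabilityResult:
    """Full separability analysis: si, all three model r^2, bootstrap p."""
    res = separability_index(M)
    res.r2_svd = fit_rank1_model(M)
    res.r2_marginal_product = fit_marginal_product(M)
    res.r2_marginal_sum = fit_marginal_sum(M)
    res.p_bootstrap = bootstrap_si_test(M, n_iter=n_iter, seed=seed)
    return res
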