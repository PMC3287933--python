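"""Parametric and permutation association tests.

* :func:`logistic_score_test` — efficient score test of the joint null
  "no genetic main effects and no gene-environment interaction" in a
  logistic model, using only the null (covariate) fit.
* :func:`hotelling_t2` — two-sample Hotelling T^2 on multivariate genotype
  or burden-score vectors.
* :func:`ge_correlation_test` — Fisher-z contrast of the genotype-exposure
  correlation between affected and unaffected groups.
* :func:`permutation_pvalue` — generic label-permutation engine, plus
  vectorized fast paths for the two screening statistics.

Permutation p-values use the add-one convention
``p = (1 + #{stat_b >= stat_obs}) / (B + 1)`` with ties counted as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats

from ._glm import ConvergenceError, SeparationError, irls_logistic
from .data_model import ValidationError

_RANK_TOL = 1e-8


@dataclass
class TestResult:
    """One test's outcome: statistic, reference distribution, p-value."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    moments: list[tuple[float, float]] | None = None  # (kappa, nu) per component
    n_used: int = 0
    p_source: str = "analytic"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValidationError(f"degrees of freedom must be positive, got {self.df}")


def results_to_frame(results: Sequence[TestResult], genes: Sequence[str] | None = None):
    """TSV-ready table; moment-matched tests serialize df as 'k1,n1;k2,n2'."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        if r.moments is not None:
            df_str = ";".join(f"{k:.6g},{n:.6g}" for k, n in r.moments)
        else:
            df_str = "" if r.df is None else f"{r.df:g}"
        rows.append(
            {
                "gene": genes[i] if genes is not None else "",
                "method": r.method,
                "statistic": r.statistic,
                "df": df_str,
                "p_value": r.p_value,
                "p_source": r.p_source,
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic score test


def _independent_columns(G: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Indices of G's columns that add rank beyond X (pivoted QR on residuals)."""
    if G.shape[1] == 0:
        return np.array([], dtype=int)
    norms = np.sqrt((G**2).sum(axis=0))
    coef, *_ = np.linalg.lstsq(X, G, rcond=None)
    R = G - X @ coef
    resid = np.sqrt((R**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(norms > 0, resid / norms, 0.0)
    cand = np.nonzero(rel > _RANK_TOL)[0]
    if cand.size == 0:
        return np.array([], dtype=int)
    _, r, piv = sla.qr(R[:, cand] / norms[cand], mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > _RANK_TOL * diag[0]).sum())
    return np.sort(cand[piv[:rank]])


def logistic_score_test(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    s: np.ndarray | None = None,
    method: str = "logistic_score",
) -> TestResult:
    """Score test of H0: no effect of Z and (optionally) of s*Z.

    The tested design is ``G = [Z, s*Z]`` (elementwise interaction columns
    appended when ``s`` is given).  Constant or collinear columns of G are
    pruned with a note and the degrees of freedom reduced accordingly.  The
    statistic is the efficient score ``U' I_eff^{-1} U`` with the score and
    information evaluated at the null fit of y on X alone; the efficient
    information subtracts the cross-information projected through the
    nuisance (covariate) block.  p comes from chi-square with df equal to
    the retained column count.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    G = Z if s is None else np.hstack([Z, Z * np.asarray(s, dtype=float)[:, None]])
    keep = _independent_columns(G, X)
    if keep.size == 0:
        raise ValidationError("no testable genetic signal: all columns degenerate")
    dropped = G.shape[1] - keep.size
    G = G[:, keep]
    _, mu = irls_logistic(y, X)
    w = mu * (1.0 - mu)
    U = G.T @ (y - mu)
    GtW = G.T * w
    XtW = X.T * w
    I_gg = GtW @ G
    I_gx = GtW @ X
    I_xx = XtW @ X
    I_eff = I_gg - I_gx @ np.linalg.solve(I_xx, I_gx.T)
    try:
        stat = float(U @ np.linalg.solve(I_eff, U))
    except np.linalg.LinAlgError:
        stat = float(U @ np.linalg.pinv(I_eff) @ U)
    df = keep.size
    p = float(stats.chi2.sf(stat, df))
    notes = {"dropped_columns": dropped} if dropped else {}
    return TestResult(method, stat, p, df=float(df), n_used=len(y), notes=notes)


# ---------------------------------------------------------------------------
# Hotelling T^2


def hotelling_t2(A: np.ndarray, B: np.ndarray, method: str = "hotelling_t2") -> TestResult:
    """Two-sample Hotelling T^2 with pooled covariance (pseudoinverse if singular).

    The parametric p uses the F transform when the pooled covariance is
    full rank; otherwise p is NaN with a note (use permutation).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("both groups must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValidationError("groups must share the same dimension")
    n_a, d = A.shape
    n_b = B.shape[0]
    N = n_a + n_b
    diff = A.mean(axis=0) - B.mean(axis=0)
    S = np.zeros((d, d))
    if n_a > 1:
        S += (n_a - 1) * np.cov(A, rowvar=False).reshape(d, d)
    if n_b > 1:
        S += (n_b - 1) * np.cov(B, rowvar=False).reshape(d, d)
    notes: dict = {}
    if N - 2 <= 0:
        raise ValidationError("need at least three samples in total")
    S /= N - 2
    rank = int(np.linalg.matrix_rank(S, tol=None)) if S.size else 0
    t2 = float(n_a * n_b / N * diff @ np.linalg.pinv(S, hermitian=True) @ diff)
    if N - 2 < d:
        notes["rank"] = "rank-deficient, permutation p only"
        p = float("nan")
    elif rank < d:
        notes["rank"] = f"pooled covariance rank {rank} < d={d}; permutation p recommended"
        p = float("nan")
    else:
        f_stat = t2 * (N - d - 1) / (d * (N - 2))
        p = float(stats.f.sf(f_stat, d, N - d - 1)) if N - d - 1 > 0 else float("nan")
    return TestResult(method, t2, p, df=float(d), n_used=N, notes=notes)


# ---------------------------------------------------------------------------
# gene-environment correlation contrast


def _fisher_z_stat(g, e, status):
    aff = status == 1
    stats_out = []
    for mask in (aff, ~aff):
        gi, ei = g[mask], e[mask]
        if mask.sum() < 4:
            raise ValidationError("each status group needs at least 4 samples")
        if np.ptp(gi) == 0 or np.ptp(ei) == 0:
            raise ValidationError("constant score or exposure within a status group")
        r = float(np.corrcoef(gi, ei)[0, 1])
        if not np.isfinite(r) or abs(r) >= 1.0 - 1e-12:
            raise ValidationError("degenerate correlation (|r| = 1)")
        stats_out.append((r, mask.sum()))
    (r_a, n_a), (r_u, n_u) = stats_out
    z = (np.arctanh(r_a) - np.arctanh(r_u)) / np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_u - 3))
    return float(z), n_a, n_u


def ge_correlation_test(
    gscore: np.ndarray,
    env: np.ndarray,
    status: np.ndarray,
    method: str = "ge_correlation",
) -> TestResult:
    """Fisher-z test of Corr(G, E | affected) = Corr(G, E | unaffected).

    statistic = (atanh r_A - atanh r_U) / sqrt(1/(n_A-3) + 1/(n_U-3)),
    referred to a standard normal (two-sided).  Within the two-stage
    pipeline the p-value is obtained by permutation instead.
    """
    g = np.asarray(gscore, dtype=float)
    e = np.asarray(env, dtype=float)
    st = np.asarray(status, dtype=int)
    z, n_a, n_u = _fisher_z_stat(g, e, st)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(method, z, p, n_used=n_a + n_u)


# ---------------------------------------------------------------------------
# permutation engine


def permutation_pvalue(
    stat_fn: Callable[[np.ndarray], float],
    status: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "permutation",
) -> TestResult:
    """Monte-Carlo permutation p-value by permuting disease status only.

    Status labels are shuffled (affected/unaffected totals preserved by
    construction); covariates and genotypes stay fixed.  ``stat_fn`` maps a
    status vector to a larger-is-more-extreme statistic (pass absolute
    values for two-sided tests).  A failing permutation draw is retried
    with a fresh one, at most 10 times.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    status = np.asarray(status)
    obs = float(stat_fn(status))
    count = 0
    for _ in range(B):
        for attempt in range(10):
            perm = rng.permutation(status)
            try:
                val = float(stat_fn(perm))
            except Exception:
                if attempt == 9:
                    raise
                continue
            break
        if val >= obs:
            count += 1
    p = (1.0 + count) / (B + 1.0)
    return TestResult(
        method, obs, p, n_used=len(status), p_source="permutation", notes={"B": B}
    )


def permuted_label_matrix(
    status: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """n x B matrix whose columns are independent permutations of status."""
    status = np.asarray(status)
    tiled = np.tile(status, (B, 1))
    return rng.permuted(tiled, axis=1).T


def _hotelling_perm_stats(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Hotelling T^2 for every label column, via the regression identity.

    With the data reduced to a full-column-rank basis, T^2 equals
    ``(N - 2) R^2 / (1 - R^2)`` where R^2 comes from regressing the 0/1
    group indicator on the data columns.  The total scatter is permutation
    invariant, so all B statistics reduce to one matrix product.
    """
    n = M.shape[0]
    Mc = M - M.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(Mc, full_matrices=False)
    keep = sv > _RANK_TOL * (sv[0] if sv.size else 1.0)
    if not keep.any():
        raise ValidationError("data matrix is constant; Hotelling test undefined")
    basis = u[:, keep]  # orthonormal columns spanning centered data
    proj = basis.T @ labels  # r x B
    ss_reg = (proj**2).sum(axis=0)
    n1 = labels.sum(axis=0).astype(float)
    ss_y = n1 * (1.0 - n1 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = ss_reg / ss_y
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return (n - 2) * r2 / (1.0 - r2)


def hotelling_permutation_test(
    M: np.ndarray,
    status: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels: np.ndarray | None = None,
    method: str = "hotelling_t2",
) -> TestResult:
    """Permutation Hotelling T^2, vectorized over all B permutations.

    ``labels`` may supply a precomputed permuted label matrix (shared
    across genes for common random numbers); otherwise one is drawn.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.ndim == 1:
        M = M[:, None]
    status = np.asarray(status, dtype=float)
    if labels is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        labels = permuted_label_matrix(status, B, rng)
    obs = float(_hotelling_perm_stats(M, status[:, None])[0])
    perm = _hotelling_perm_stats(M, labels)
    p = (1.0 + int((perm >= obs).sum())) / (labels.shape[1] + 1.0)
    return TestResult(
        method, obs, p, df=float(M.shape[1]), n_used=len(status),
        p_source="permutation", notes={"B": labels.shape[1]},
    )


def _ge_perm_stats(g: np.ndarray, e: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """|Fisher-z contrast| for every label column via group-sum algebra."""
    n = g.shape[0]
    cols = np.column_stack([g, e, g * g, e * e, g * e])  # n x 5
    total = cols.sum(axis=0)
    S_a = labels.T @ cols  # B x 5 sums within the "affected" group
    n_a = labels.sum(axis=0).astype(float)
    n_u = n - n_a
    S_u = total[None, :] - S_a

    def _corr(S, m):
        sg, se, sgg, see, sge = S.T
        cov = sge - sg * se / m
        vg = sgg - sg**2 / m
        ve = see - se**2 / m
        with np.errstate(divide="ignore", invalid="ignore"):
            return cov / np.sqrt(vg * ve)

    r_a = _corr(S_a, n_a)
    r_u = _corr(S_u, n_u)
    bad = (
        ~np.isfinite(r_a)
        | ~np.isfinite(r_u)
        | (np.abs(r_a) >= 1.0 - 1e-12)
        | (np.abs(r_u) >= 1.0 - 1e-12)
        | (n_a < 4)
        | (n_u < 4)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.arctanh(np.where(bad, 0.0, r_a)) - np.arctanh(np.where(bad, 0.0, r_u))) / np.sqrt(
            1.0 / (n_a - 3) + 1.0 / (n_u - 3)
        )
    z = np.abs(z)
    z[bad] = np.nan
    return z


def ge_correlation_permutation_test(
    gscore: np.ndarray,
    env: np.ndarray,
    status: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels: np.ndarray | None = None,
    method: str = "ge_correlation",
) -> TestResult:
    """Permutation p for the (two-sided) Fisher-z G-E contrast, vectorized."""
    g = np.asarray(gscore, dtype=float)
    e = np.asarray(env, dtype=float)
    status = np.asarray(status, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = permuted_label_matrix(status, B, rng)
    z_obs, _, _ = _fisher_z_stat(g, e, status.astype(int))
    obs = abs(z_obs)
    perm = _ge_perm_stats(g, e, labels)
    # degenerate permutations (constant within a group): redraw, bounded retries
    for _ in range(10):
        bad = ~np.isfinite(perm)
        if not bad.any():
            break
        fresh = permuted_label_matrix(status, int(bad.sum()), rng)
        perm[bad] = _ge_perm_stats(g, e, fresh)
    if not np.isfinite(perm).all():
        raise ValidationError("permutation statistics repeatedly degenerate")
    p = (1.0 + int((perm >= obs).sum())) / (perm.size + 1.0)
    return TestResult(
        method, obs, p, n_used=len(status), p_source="permutation",
        notes={"B": perm.size},
    )


__all__ = [
    "TestResult",
    "results_to_frame",
    "logistic_score_test",
    "hotelling_t2",
    "ge_correlation_test",
    "permutation_pvalue",
    "permuted_label_matrix",
    "hotelling_permutation_test",
    "ge_correlation_permutation_test",
    "ConvergenceError",
    "SeparationError",
]
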