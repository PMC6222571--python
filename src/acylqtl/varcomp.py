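"""Variance-component partitioning among segregating loci (Type-3 analogue).

Each locus enters as a random factor through its per-sample binary indicator
(recessive class vs not).  Estimation is the classical Type-III
method-of-moments: compute the Type-III sum of squares for every factor in
the main-effects crossed model, equate each observed SS (and the residual SS)
to its expectation under the all-random model, and solve the resulting linear
system for the variance components.  Negative solutions are truncated to zero
before proportions are formed, with the untruncated values retained for
inspection.

The fixed-effects side mirrors the companion multiple-regression step: every
locus indicator in one OLS model, reporting the trait-unit shift attributable
to each recessive class with its two-sided p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError

log = logging.getLogger(__name__)


@dataclass
class VarianceDecomposition:
    """Per-factor variance estimates and percent-of-total proportions."""

    components: pd.DataFrame  # factor, variance, proportion_pct (incl. Residual)
    raw_components: pd.DataFrame  # untruncated solutions
    method: str  # "type3" or "type1_fallback"
    trait: str = "trait"
    dropped: tuple[str, ...] = ()


def _proj_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of col(M) via SVD (rank-safe)."""
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return u[:, :0]
    rank = int((s > s[0] * 1e-10).sum())
    return u[:, :rank]


def _ss_and_traces(
    y: np.ndarray, Zs: dict[str, np.ndarray], quad_pairs: list[tuple[np.ndarray, np.ndarray]]
):
    """SS and EMS coefficients for quadratic forms Q = P_full - P_reduced.

    ``quad_pairs`` holds (basis_full, basis_reduced) orthonormal bases; the
    expectation of y'Qy under the all-random model is
    sum_g sigma2_g * tr(Q Z_g Z_g') + sigma2_e * tr(Q).
    """
    rows = []
    ss = []
    names = list(Zs)
    for Qf, Qr in quad_pairs:
        ss_val = float(np.sum((Qf.T @ y) ** 2) - np.sum((Qr.T @ y) ** 2))
        coefs = []
        for g in names:
            Z = Zs[g]
            coefs.append(float(np.sum((Qf.T @ Z) ** 2) - np.sum((Qr.T @ Z) ** 2)))
        coefs.append(float(Qf.shape[1] - Qr.shape[1]))  # tr(Q) = rank difference
        rows.append(coefs)
        ss.append(ss_val)
    return np.array(ss), np.array(rows)


def decompose_variance(
    y,
    factors: pd.DataFrame,
    trait: str = "trait",
    truncate: bool = True,
) -> VarianceDecomposition:
    """Partition trait variance among binary random factors plus residual.

    ``factors`` is a samples x factors DataFrame of 0/1 indicators.  Factors
    with a single observed level are dropped with a warning.  If the
    expected-mean-square system is singular the estimator falls back to a
    sequential (Type-I) decomposition, also via method of moments.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(factors):
        raise InvalidInputError("y and factors must have matching length")
    keep, dropped = [], []
    for name in factors.columns:
        if factors[name].nunique() < 2:
            dropped.append(name)
        else:
            keep.append(name)
    if dropped:
        log.warning("dropping single-level factor(s): %s", ", ".join(dropped))
    if not keep:
        raise InvalidInputError("no factor with two observed levels")

    n = len(y)
    F = factors[keep].to_numpy(dtype=float)
    # two-level indicator matrices Z_g (n x 2): Z Z' is the same-level kernel
    Zs = {
        name: np.column_stack([F[:, j], 1.0 - F[:, j]]) for j, name in enumerate(keep)
    }
    ones = np.ones((n, 1))
    X_full = np.column_stack([ones, F])
    B_full = _proj_basis(X_full)
    r_full = B_full.shape[1]

    method = "type3"
    quad_pairs = []
    for j, name in enumerate(keep):
        X_red = np.column_stack([ones, np.delete(F, j, axis=1)])
        quad_pairs.append((B_full, _proj_basis(X_red)))
    ss, coefs = _ss_and_traces(y, Zs, quad_pairs)

    # residual row: E[SSE] = sum_g sigma2_g tr((I-P)ZZ') + sigma2_e (n - r)
    sse = float(y @ y - np.sum((B_full.T @ y) ** 2))
    res_coefs = []
    for name in keep:
        Z = Zs[name]
        res_coefs.append(float(np.sum(Z * Z) - np.sum((B_full.T @ Z) ** 2)))
    res_coefs.append(float(n - r_full))

    A = np.vstack([coefs, res_coefs])
    b = np.concatenate([ss, [sse]])
    try:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned EMS system")
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        method = "type1_fallback"
        log.warning("Type-3 EMS system singular; falling back to sequential SS")
        quad_pairs = []
        prev = _proj_basis(ones)
        for j in range(len(keep)):
            cur = _proj_basis(np.column_stack([ones, F[:, : j + 1]]))
            quad_pairs.append((cur, prev))
            prev = cur
        ss, coefs = _ss_and_traces(y, Zs, quad_pairs)
        A = np.vstack([coefs, res_coefs])
        b = np.concatenate([ss, [sse]])
        sol = np.linalg.lstsq(A, b, rcond=None)[0]

    names = keep + ["Residual"]
    raw = pd.DataFrame({"factor": names, "variance": sol})
    comp = sol.copy()
    if truncate:
        comp = np.maximum(comp, 0.0)
    total = comp.sum()
    props = 100.0 * comp / total if total > 0 else np.full_like(comp, np.nan)
    components = pd.DataFrame(
        {"factor": names, "variance": comp, "proportion_pct": props}
    )
    return VarianceDecomposition(
        components=components,
        raw_components=raw,
        method=method,
        trait=trait,
        dropped=tuple(dropped),
    )


@dataclass
class FixedEffectsSummary:
    """OLS effect estimates per recessive-class indicator."""

    table: pd.DataFrame  # factor, estimate, se, t, p
    aliased: tuple[str, ...]
    trait: str = "trait"


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on the preceding ones (incremental rank)."""
    aliased = []
    cols = [np.ones(X.shape[0])]
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) == len(cols):
            aliased.append(name)
        else:
            cols.append(X[:, j])
    return aliased


def fixed_effects_summary(
    y, factors: pd.DataFrame, trait: str = "trait"
) -> FixedEffectsSummary:
    """Multiple regression of the trait on all locus indicators at once.

    Rank-deficient designs are not silently reduced: aliased factors are
    reported and their coefficient rows are NaN.
    """
    y = np.asarray(y, dtype=float)
    names = list(factors.columns)
    X = factors.to_numpy(dtype=float)
    aliased = _aliased_columns(X, names)
    usable = [nm for nm in names if nm not in aliased]
    design = sm.add_constant(factors[usable], has_constant="add")
    fit = sm.OLS(y, design).fit()
    rows = []
    for nm in names:
        if nm in aliased:
            rows.append({"factor": nm, "estimate": np.nan, "se": np.nan,
                         "t": np.nan, "p": np.nan})
        else:
            rows.append(
                {
                    "factor": nm,
                    "estimate": float(fit.params[nm]),
                    "se": float(fit.bse[nm]),
                    "t": float(fit.tvalues[nm]),
                    "p": float(fit.pvalues[nm]),
                }
            )
    return FixedEffectsSummary(
        table=pd.DataFrame(rows), aliased=tuple(aliased), trait=trait
    )
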